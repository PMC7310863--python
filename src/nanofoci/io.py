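"""Readers and writers for the delimited-text, JSON and TIFF interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from nanofoci.foci_class import AxisPolyline
from nanofoci.nanoseg import validate_localizations


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localisation table (CSV/TSV with named columns, nm units)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"localisation file not found: {path}")
    try:
        table = pd.read_csv(path, sep=None, engine="python")
        return validate_localizations(table).copy()
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot parse localisation file {path}: {exc}") from exc


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.4f")


def read_roi_centres(path: str | Path) -> pd.DataFrame:
    """ROI centre list: delimited text with x_nm, y_nm and optional metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI centre file not found: {path}")
    centres = pd.read_csv(path, sep=None, engine="python")
    for col in ("x_nm", "y_nm"):
        if col not in centres.columns:
            raise ValueError(f"ROI centre file {path} lacks column {col}")
    return centres


def read_polylines(path: str | Path) -> list[AxisPolyline]:
    """Axis polylines from JSON: a list of objects or bare vertex lists.

    Each entry is either ``[[x, y], ...]`` (nm) or
    ``{"points": [[x, y], ...], "nucleus": ..., "synapsed": ...}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"polyline file not found: {path}")
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for entry in raw:
        if isinstance(entry, dict):
            out.append(AxisPolyline(
                points=np.asarray(entry["points"], dtype=float),
                nucleus=str(entry.get("nucleus", "")),
                synapsed=entry.get("synapsed"),
            ))
        else:
            out.append(AxisPolyline(points=np.asarray(entry, dtype=float)))
    return out


def write_polylines(polylines: list[AxisPolyline], path: str | Path) -> None:
    payload = [{
        "points": p.points.tolist(),
        "nucleus": p.nucleus,
        "synapsed": p.synapsed,
    } for p in polylines]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    return tifffile.imread(path)


def write_image(image: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path).astype(bool)


def read_config_file(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)
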