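"""Pipeline orchestration, configuration, reporting and group statistics."""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from nanofoci import io
from nanofoci.foci_class import (
    AxisPolyline, FocusConfiguration, analyze_configuration,
    axis_min_distance, collapse_label,
)
from nanofoci.nanoseg import RoiRecord, extract_rois, roi_qc, segment_channels
from nanofoci.rotalign import stack_distances

log = logging.getLogger("nanofoci")


@dataclass
class PipelineConfig:
    """Every tunable of the analysis chain, with its standard default.

    All defaults mirror the published analysis settings: 20 nm KDE
    bandwidth on a 5 nm grid, 0.2 events/nm^2 density threshold, 50 pixel
    minimum nanofocus area, 300 nm ROI radius, 25% ROI overlap cutoff,
    50-localisation ROI floor, 90/100 confocal detection tolerances,
    110 nm confocal blur, 100 nm distance bins with a 3.4 um rest class,
    1 um axis-proximity cutoff, 50 CSR simulations per nucleus and 200
    simulated foci per model grid cell.
    """

    kde_bandwidth: float = 20.0
    kde_pixel: float = 5.0
    density_threshold: float = 0.2
    min_area: int = 50
    roi_radius: float = 300.0
    overlap_cutoff: float = 0.25
    min_localisations: int = 50
    min_locs_per_channel: bool = False
    noise_tolerance_dmc1: float = 90.0
    noise_tolerance_rad51: float = 100.0
    blur_sigma: float = 110.0
    confocal_pixel: float = 99.0
    bin_width: float = 100.0
    rest_cutoff: float = 3400.0
    axis_near_cutoff: float = 1000.0
    n_sims: int = 50
    n_per_cell: int = 200
    connectivity: int = 8
    seed: int = 0

    def validate(self) -> None:
        positive = ("kde_bandwidth", "kde_pixel", "density_threshold",
                    "min_area", "roi_radius", "overlap_cutoff",
                    "min_localisations", "noise_tolerance_dmc1",
                    "noise_tolerance_rad51", "blur_sigma", "confocal_pixel",
                    "bin_width", "rest_cutoff", "axis_near_cutoff",
                    "n_sims", "n_per_cell")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be > 0")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls(**io.read_config_file(path))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory result of a pipeline run (also written to the run directory)."""

    rois: list[RoiRecord]
    configs: list[FocusConfiguration]
    exclusions: list[dict]
    config_table: pd.DataFrame
    nanofocus_table: pd.DataFrame
    summary: dict
    outdir: Path | None = None


def analyze_rois(
    rois: list[RoiRecord],
    config: PipelineConfig,
    polylines: list[AxisPolyline] | None = None,
) -> tuple[list[FocusConfiguration], pd.DataFrame, pd.DataFrame]:
    """Segment, classify and tabulate a list of quality-controlled ROIs."""
    configs = []
    nf_rows = []
    cfg_rows = []
    for roi in rois:
        margin = 3.0 * config.kde_bandwidth
        bounds = (roi.centre - roi.radius - margin,
                  roi.centre + roi.radius + margin)
        nanofoci = segment_channels(
            roi.events, bandwidth=config.kde_bandwidth, pixel=config.kde_pixel,
            threshold=config.density_threshold, min_area=config.min_area,
            bounds=bounds, connectivity=config.connectivity)
        fc = analyze_configuration(
            roi.id, nanofoci["DMC1"] + nanofoci["RAD51"],
            stage=roi.stage, synapsed=roi.synapsed)
        configs.append(fc)
        for idx, nf in enumerate(fc.nanofoci):
            axis_nm, near = (np.nan, None)
            if polylines:
                axis_nm, near = axis_min_distance(
                    nf, polylines, near_cutoff=config.axis_near_cutoff)
            nf_rows.append({
                "roi": roi.id, "stage": roi.stage, "channel": nf.channel,
                "index": idx, "role": fc.roles.get(idx, ""),
                "area_px": nf.area_px, "area_nm2": nf.area_nm2,
                "com_x_nm": nf.com_nm[0], "com_y_nm": nf.com_nm[1],
                "n_locs": nf.n_locs, "axis_nm": axis_nm, "near_axis": near,
            })
        cfg_rows.append({
            "roi": roi.id, "nucleus": roi.nucleus, "stage": roi.stage,
            "synapsed": roi.synapsed, "n_D": fc.n_D, "n_R": fc.n_R,
            "label": fc.label, "group": collapse_label(fc.label),
            "morphology": fc.morphology,
            "min_dist_nm": fc.min_dist, "max_dist_nm": fc.max_dist,
            "n_locs": roi.n_locs,
        })
    cfg_cols = ["roi", "nucleus", "stage", "synapsed", "n_D", "n_R", "label",
                "group", "morphology", "min_dist_nm", "max_dist_nm", "n_locs"]
    nf_cols = ["roi", "stage", "channel", "index", "role", "area_px",
               "area_nm2", "com_x_nm", "com_y_nm", "n_locs", "axis_nm",
               "near_axis"]
    return (configs, pd.DataFrame(cfg_rows, columns=cfg_cols),
            pd.DataFrame(nf_rows, columns=nf_cols))


def summarize_configs(config_table: pd.DataFrame) -> dict:
    """Per-stage DxRy group fractions and morphology fractions."""
    summary: dict = {"n_foci": int(len(config_table))}
    if not len(config_table):
        return summary
    overall = config_table["group"].value_counts(normalize=True)
    summary["dxry_fractions"] = {k: round(float(v), 4)
                                 for k, v in overall.sort_index().items()}
    per_stage = {}
    for stage, sub in config_table.groupby("stage"):
        frac = sub["group"].value_counts(normalize=True)
        per_stage[str(stage)] = {k: round(float(v), 4)
                                 for k, v in frac.sort_index().items()}
    summary["dxry_fractions_by_stage"] = per_stage
    morph = config_table["morphology"].value_counts(normalize=True)
    summary["morphology_fractions"] = {k: round(float(v), 4)
                                       for k, v in morph.sort_index().items()}
    return summary


def run_pipeline(
    config: PipelineConfig,
    localizations,
    roi_centres,
    polylines=None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the dSTORM analysis chain and write the run directory.

    ``localizations`` / ``roi_centres`` / ``polylines`` may be paths or
    already-loaded objects.  The run directory receives the per-focus
    configuration table, the per-nanofocus feature table, the per-stage
    distance summary, the QC exclusion log, a machine-readable summary,
    the echoed configuration (including the seed) and a manifest.  On
    failure, partially written outputs are removed.
    """
    config.validate()
    if isinstance(localizations, (str, Path)):
        localizations = io.read_localizations(localizations)
    if isinstance(roi_centres, (str, Path)):
        roi_centres = io.read_roi_centres(roi_centres)
    if isinstance(polylines, (str, Path)):
        polylines = io.read_polylines(polylines)

    out = Path(outdir) if outdir is not None else None
    created = out is not None and not out.exists()
    try:
        rois = extract_rois(localizations, roi_centres, radius=config.roi_radius)
        kept, exclusions = roi_qc(
            rois, overlap_cutoff=config.overlap_cutoff,
            min_locs=config.min_localisations,
            per_channel=config.min_locs_per_channel)
        log.info("ROIs: %d selected, %d kept, %d excluded",
                 len(rois), len(kept), len(exclusions))
        configs, config_table, nf_table = analyze_rois(kept, config, polylines)
        summary = summarize_configs(config_table)
        by_stage: dict[str, list[FocusConfiguration]] = {}
        for fc in configs:
            by_stage.setdefault(fc.stage or "all", []).append(fc)
        distances = stack_distances(by_stage)
        result = PipelineResult(kept, configs, exclusions, config_table,
                                nf_table, summary, out)
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            config_table.to_csv(out / "configurations.csv", index=False,
                                float_format="%.4f")
            nf_table.to_csv(out / "nanofoci.csv", index=False,
                            float_format="%.4f")
            distances.to_csv(out / "stage_distances.csv", index=False,
                             float_format="%.4f")
            pd.DataFrame(exclusions, columns=["roi", "rule", "detail"]).to_csv(
                out / "exclusions.csv", index=False)
            with open(out / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            config.to_yaml(out / "run_config.yaml")
            manifest = sorted(p.name for p in out.iterdir())
            with open(out / "manifest.json", "w") as fh:
                json.dump({"files": manifest}, fh, indent=1)
        return result
    except Exception:
        if out is not None and out.exists() and created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def compare_groups(
    table: pd.DataFrame,
    value: str,
    group: str,
    test: str = "t",
    pair: str | None = None,
) -> pd.DataFrame:
    """Pairwise group comparisons with the standard two-sample tests.

    ``test`` is one of ``t`` (Student's two-sample, two-sided),
    ``mannwhitney`` (Mann-Whitney U) or ``paired_t`` (two-sided paired t;
    requires ``pair``, the column identifying the within-pair unit, e.g.
    the nucleus for synapsed-versus-unsynapsed comparisons).  Groups with
    fewer than two observations are skipped with a note.  A p-value below
    0.05 is conventionally considered significant; no multiple-testing
    correction is applied.
    """
    if test not in ("t", "mannwhitney", "paired_t"):
        raise ValueError(f"unknown test {test!r}")
    if test == "paired_t" and pair is None:
        raise ValueError("paired_t requires the pairing column via `pair`")
    groups = list(table.groupby(group))
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for (ga, sub_a), (gb, sub_b) in combinations(groups, 2):
        row = {"group_a": ga, "group_b": gb, "test": test,
               "n_a": len(sub_a), "n_b": len(sub_b),
               "statistic": np.nan, "p_value": np.nan, "note": ""}
        if test == "paired_t":
            merged = pd.merge(sub_a[[pair, value]], sub_b[[pair, value]],
                              on=pair, suffixes=("_a", "_b")).dropna()
            row["n_a"] = row["n_b"] = len(merged)
            if len(merged) < 2:
                row["note"] = "skipped: fewer than 2 complete pairs"
            else:
                res = stats.ttest_rel(merged[f"{value}_a"],
                                      merged[f"{value}_b"])
                row["statistic"], row["p_value"] = res.statistic, res.pvalue
        else:
            a = sub_a[value].dropna().to_numpy()
            b = sub_b[value].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                row["note"] = "skipped: group smaller than 2"
            elif test == "t":
                res = stats.ttest_ind(a, b)
                row["statistic"], row["p_value"] = res.statistic, res.pvalue
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                row["statistic"], row["p_value"] = res.statistic, res.pvalue
        rows.append(row)
    return pd.DataFrame(rows)
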