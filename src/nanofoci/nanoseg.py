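"""dSTORM ROI management, kernel-density estimation and nanofocus segmentation.

A repair focus is analysed inside a circular region of interest (ROI) of
300 nm radius.  Localisations of each colour channel are turned into an
absolute density surface (events/nm^2) by binned kernel density estimation
with a 20 nm Gaussian bandwidth on a 5 nm grid, and contiguous regions
above a density threshold of 0.2 events/nm^2 (5 events per 5 nm pixel)
with an area of at least 50 pixels are segmented as *nanofoci* -- the
sub-focus unit of all downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label as nd_label
from scipy.spatial import cKDTree

DEFAULT_BANDWIDTH = 20.0   # nm, approximate average localisation precision
DEFAULT_PIXEL = 5.0        # nm, grid spacing of the density raster
DEFAULT_THRESHOLD = 0.2    # events/nm^2 == 5 events per 5 nm pixel
DEFAULT_MIN_AREA = 50      # pixels; smaller components are background
ROI_RADIUS = 300.0         # nm

_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)

REQUIRED_COLUMNS = ("x_nm", "y_nm", "channel")


def validate_localizations(table: pd.DataFrame) -> pd.DataFrame:
    """Check a localisation table for the required columns and finiteness."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"localisation table lacks columns: {missing}")
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("localisation coordinates must be finite")
    return table


@dataclass
class RoiRecord:
    """A circular 300 nm-radius selection around one repair focus."""

    id: str
    centre: np.ndarray                  # (2,) nm
    events: pd.DataFrame                # member localisations (all channels)
    radius: float = ROI_RADIUS
    nucleus: str = ""
    stage: str = ""
    synapsed: bool | None = None

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(2)

    @property
    def n_locs(self) -> int:
        return len(self.events)

    def channel_events(self, channel: str) -> pd.DataFrame:
        return self.events[self.events["channel"] == channel]

    def channel_counts(self) -> dict[str, int]:
        return self.events["channel"].value_counts().to_dict()


def extract_rois(
    table: pd.DataFrame,
    centres: pd.DataFrame | np.ndarray,
    radius: float = ROI_RADIUS,
) -> list[RoiRecord]:
    """Select all localisations within ``radius`` (closed disc) of each centre.

    ``centres`` may be an (n, 2) array or a DataFrame with ``x_nm, y_nm``
    and optional ``id, nucleus, stage, synapsed`` metadata columns.  Event
    rows keep their index in ``table`` so overlap between ROIs can be
    assessed later.
    """
    validate_localizations(table)
    if isinstance(centres, pd.DataFrame):
        meta = centres
        xy_c = centres[["x_nm", "y_nm"]].to_numpy(dtype=float)
    else:
        xy_c = np.asarray(centres, dtype=float).reshape(-1, 2)
        meta = pd.DataFrame({"x_nm": xy_c[:, 0], "y_nm": xy_c[:, 1]})
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    tree = cKDTree(xy) if len(xy) else None
    rois = []
    for i in range(len(xy_c)):
        if tree is not None:
            # closed disc: points at exactly `radius` are members
            idx = tree.query_ball_point(xy_c[i], radius + 1e-9)
            events = table.iloc[sorted(idx)]
        else:
            events = table.iloc[[]]
        row = meta.iloc[i]
        rois.append(RoiRecord(
            id=str(row["id"]) if "id" in meta.columns else f"roi_{i:04d}",
            centre=xy_c[i],
            events=events,
            radius=radius,
            nucleus=str(row.get("nucleus", "")),
            stage=str(row.get("stage", "")),
            synapsed=bool(row["synapsed"]) if "synapsed" in meta.columns
            and not pd.isna(row["synapsed"]) else None,
        ))
    return rois


def roi_qc(
    rois: list[RoiRecord],
    overlap_cutoff: float = 0.25,
    min_locs: int = 50,
    per_channel: bool = False,
) -> tuple[list[RoiRecord], list[dict]]:
    """Apply the two ROI exclusion rules and log what fired.

    ROI pairs sharing more than ``overlap_cutoff`` of their localisations
    (fraction relative to the smaller ROI) are both removed, and ROIs with
    fewer than ``min_locs`` localisations are removed.  The count floor is
    applied to the ROI total over both channels by default; with
    ``per_channel=True`` every channel must individually reach the floor.
    """
    excluded: dict[str, dict] = {}
    index_sets = {r.id: set(r.events.index) for r in rois}
    for a, b in combinations(rois, 2):
        sa, sb = index_sets[a.id], index_sets[b.id]
        denom = min(len(sa), len(sb))
        if denom == 0:
            continue
        frac = len(sa & sb) / denom
        if frac > overlap_cutoff:
            for r, other in ((a, b), (b, a)):
                excluded.setdefault(r.id, {
                    "roi": r.id, "rule": "overlap",
                    "detail": f"shares {frac:.1%} of localisations with {other.id}",
                })
    for r in rois:
        if r.id in excluded:
            continue
        counts = r.channel_counts()
        if per_channel:
            low = min(counts.values()) if counts else 0
        else:
            low = r.n_locs
        if low < min_locs:
            excluded[r.id] = {
                "roi": r.id, "rule": "min_localisations",
                "detail": f"{low} < {min_locs}",
            }
    kept = [r for r in rois if r.id not in excluded]
    return kept, list(excluded.values())


@dataclass
class DensityMap:
    """Absolute localisation density (events/nm^2) on a regular grid.

    ``origin`` is the nm coordinate of the lower-left corner of pixel
    (0, 0); the centre of pixel (row i, col j) is at
    ``origin + (j + 0.5, i + 0.5) * pixel_size``.
    """

    values: np.ndarray
    pixel_size: float
    origin: np.ndarray          # (2,) nm, (x0, y0)
    n_points: int
    channel: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)

    @property
    def total_mass(self) -> float:
        """Integrated density; equals n_points up to boundary truncation."""
        return float(self.values.sum() * self.pixel_size**2)

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return xs, ys


def kde_density(
    points_nm: np.ndarray,
    bandwidth: float = DEFAULT_BANDWIDTH,
    pixel: float = DEFAULT_PIXEL,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    margin: float | None = None,
    channel: str = "",
) -> DensityMap:
    """Binned Gaussian KDE of 2D points, scaled to events/nm^2.

    Points are histogrammed on a ``pixel``-spaced grid and smoothed with an
    isotropic Gaussian of standard deviation ``bandwidth``; the kernel is
    truncated at four bandwidths (relative error < 1e-4 of the peak).  The
    result integrates to the number of points up to boundary truncation,
    so thresholds have an absolute density meaning.  ``bounds`` fixes the
    grid (lo, hi in nm); by default the grid covers the data plus a
    three-bandwidth margin.
    """
    pts = np.asarray(points_nm, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("cannot estimate a density from zero events")
    if bandwidth <= 0 or pixel <= 0:
        raise ValueError("bandwidth and pixel must be > 0")
    margin = 3.0 * bandwidth if margin is None else margin
    if bounds is None:
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / pixel)))
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / pixel)))
    ix = np.floor((pts[:, 0] - lo[0]) / pixel).astype(int)
    iy = np.floor((pts[:, 1] - lo[1]) / pixel).astype(int)
    ok = (ix >= 0) & (iy >= 0) & (ix < nx) & (iy < ny)
    hist = np.zeros((ny, nx), dtype=float)
    np.add.at(hist, (iy[ok], ix[ok]), 1.0)
    dens = gaussian_filter(hist, sigma=bandwidth / pixel, mode="constant",
                           truncate=4.0) / pixel**2
    return DensityMap(dens, pixel, lo, n_points=len(pts), channel=channel)


def kde_map(
    roi: RoiRecord,
    channel: str,
    bandwidth: float = DEFAULT_BANDWIDTH,
    pixel: float = DEFAULT_PIXEL,
) -> DensityMap:
    """Density map of one ROI channel on a grid covering the ROI plus margin."""
    events = roi.channel_events(channel)
    if len(events) == 0:
        raise ValueError(f"ROI {roi.id} has no events in channel {channel}")
    margin = 3.0 * bandwidth
    lo = roi.centre - roi.radius - margin
    hi = roi.centre + roi.radius + margin
    return kde_density(events[["x_nm", "y_nm"]].to_numpy(dtype=float),
                       bandwidth=bandwidth, pixel=pixel, bounds=(lo, hi),
                       channel=channel)


@dataclass
class Nanofocus:
    """A connected above-threshold region of the density map."""

    channel: str
    mask: np.ndarray            # boolean raster on the density grid
    pixel_size: float
    origin: np.ndarray          # grid origin in nm
    area_px: int
    com_nm: np.ndarray          # density-weighted centre of mass, (x, y) nm
    n_locs: int                 # events whose pixel lies inside the mask
    label_id: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        self.com_nm = np.asarray(self.com_nm, dtype=float).reshape(2)

    @property
    def area_nm2(self) -> float:
        return self.area_px * self.pixel_size**2


def segment_nanofoci(
    density: DensityMap,
    threshold: float = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
    events_nm: np.ndarray | None = None,
    connectivity: int = 8,
) -> list[Nanofocus]:
    """Segment a density map into nanofoci.

    Connected components (8-connected by default) of
    ``density >= threshold`` with at least ``min_area`` pixels become
    nanofoci; smaller components are treated as background.  The centre of
    mass is density-weighted.  When the originating events are supplied,
    each nanofocus also counts the events falling inside its mask.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _EIGHT if connectivity == 8 else _FOUR
    above = density.values >= threshold
    lab, n = nd_label(above, structure=structure)
    px = density.pixel_size
    out: list[Nanofocus] = []
    if events_nm is not None:
        ev = np.asarray(events_nm, dtype=float).reshape(-1, 2)
        ex = np.floor((ev[:, 0] - density.origin[0]) / px).astype(int)
        ey = np.floor((ev[:, 1] - density.origin[1]) / px).astype(int)
        ny, nx = lab.shape
        in_grid = (ex >= 0) & (ey >= 0) & (ex < nx) & (ey < ny)
        ev_labels = np.zeros(len(ev), dtype=int)
        ev_labels[in_grid] = lab[ey[in_grid], ex[in_grid]]
    for i in range(1, n + 1):
        mask = lab == i
        area = int(mask.sum())
        if area < min_area:
            continue
        w = density.values * mask
        total = w.sum()
        iy, ix = np.nonzero(mask)
        cx = (w[iy, ix] * (ix + 0.5)).sum() / total * px + density.origin[0]
        cy = (w[iy, ix] * (iy + 0.5)).sum() / total * px + density.origin[1]
        n_locs = int((ev_labels == i).sum()) if events_nm is not None else 0
        out.append(Nanofocus(
            channel=density.channel, mask=mask, pixel_size=px,
            origin=density.origin, area_px=area,
            com_nm=np.array([cx, cy]), n_locs=n_locs, label_id=i,
        ))
    return out


def segment_channels(
    events: pd.DataFrame,
    channels: tuple[str, str] = ("DMC1", "RAD51"),
    bandwidth: float = DEFAULT_BANDWIDTH,
    pixel: float = DEFAULT_PIXEL,
    threshold: float = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    connectivity: int = 8,
) -> dict[str, list[Nanofocus]]:
    """Segment both channels of one focus on a single shared grid.

    A common grid (covering all events of all channels plus a
    three-bandwidth margin, unless ``bounds`` is given) keeps the binary
    masks of the two channels pixel-aligned, which the morphology rules
    rely on.  Channels without events yield an empty nanofocus list.
    """
    validate_localizations(events)
    xy = events[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if bounds is None:
        if len(xy) == 0:
            return {c: [] for c in channels}
        margin = 3.0 * bandwidth
        bounds = (xy.min(axis=0) - margin, xy.max(axis=0) + margin)
    out: dict[str, list[Nanofocus]] = {}
    for ch in channels:
        ch_xy = xy[(events["channel"] == ch).to_numpy()]
        if len(ch_xy) == 0:
            out[ch] = []
            continue
        dens = kde_density(ch_xy, bandwidth=bandwidth, pixel=pixel,
                           bounds=bounds, channel=ch)
        out[ch] = segment_nanofoci(dens, threshold=threshold,
                                   min_area=min_area, events_nm=ch_xy,
                                   connectivity=connectivity)
    return out
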