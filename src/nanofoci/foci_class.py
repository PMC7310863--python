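"""Per-focus configuration analytics.

Given the segmented nanofoci of one repair focus this module derives the
DxRy stoichiometry label (x DMC1, y RAD51 nanofoci), the minimum and
maximum centre-of-mass distances, close/far roles in the asymmetric D2R1
and D1R2 configurations, a deterministic rule-based morphology class, and
distances of nanofoci to the chromosome-axis polylines.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.measure import regionprops

from nanofoci.nanoseg import Nanofocus

MAIN_LABELS = ("D1R1", "D2R1", "D1R2", "D2R2")

MORPHOLOGIES = ("simple", "complex", "separate", "bridge_D2R1",
                "bridge_D1R2", "paired", "unclassified")

AXIS_NEAR_CUTOFF = 1000.0  # nm; farther nanofoci are not on an axis


@dataclass
class AxisPolyline:
    """A manually traced synaptonemal-complex axis as an ordered polyline."""

    points: np.ndarray                 # (k, 2) nm
    nucleus: str = ""
    synapsed: bool | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 2:
            raise ValueError("axis polyline needs at least 2 points")
        if not np.isfinite(self.points).all():
            raise ValueError("axis polyline coordinates must be finite")


@dataclass
class FocusConfiguration:
    """The analysed state of one repair focus (one ROI)."""

    roi_id: str
    nanofoci: list[Nanofocus]
    stage: str = ""
    synapsed: bool | None = None
    label: str = ""
    min_dist: float | None = None      # nm, over inter-channel pairs
    max_dist: float | None = None      # nm, over all nanofocus pairs
    roles: dict[int, str] = dc_field(default_factory=dict)  # index -> role
    morphology: str = ""

    @property
    def n_D(self) -> int:
        return sum(1 for nf in self.nanofoci if nf.channel == "DMC1")

    @property
    def n_R(self) -> int:
        return sum(1 for nf in self.nanofoci if nf.channel == "RAD51")

    def by_channel(self, channel: str) -> list[tuple[int, Nanofocus]]:
        return [(i, nf) for i, nf in enumerate(self.nanofoci)
                if nf.channel == channel]

    def role_nanofocus(self, role: str) -> Nanofocus | None:
        for i, r in self.roles.items():
            if r == role:
                return self.nanofoci[i]
        return None


def classify_dxry(config: FocusConfiguration) -> str:
    """Stoichiometry label ``D{n_D}R{n_R}`` from the nanofocus counts."""
    return f"D{config.n_D}R{config.n_R}"


def collapse_label(label: str) -> str:
    """Collapse rare combinations into ``rest`` for summary tables."""
    return label if label in MAIN_LABELS else "rest"


def inter_channel_distances(
    config: FocusConfiguration,
) -> tuple[float, float, list[tuple[int, int, float]]]:
    """Minimum and maximum centre-of-mass distances within one focus.

    The minimum is taken over DMC1-RAD51 (inter-channel) pairs only; the
    maximum over *all* nanofocus pairs, same-channel pairs included, so
    that e.g. the DMC1-DMC1 separation of a D2R1 configuration sets its
    maximum.  Returns ``(min, max, pairs)`` where ``pairs`` lists every
    pair as ``(index_a, index_b, distance)``.  Raises when either channel
    has no nanofocus (the minimum would be undefined).
    """
    d_idx = config.by_channel("DMC1")
    r_idx = config.by_channel("RAD51")
    if not d_idx or not r_idx:
        raise ValueError(
            f"focus {config.roi_id}: inter-channel minimum undefined "
            f"(D={len(d_idx)}, R={len(r_idx)})")
    coms = np.array([nf.com_nm for nf in config.nanofoci])
    pairs: list[tuple[int, int, float]] = []
    for i in range(len(coms)):
        for j in range(i + 1, len(coms)):
            pairs.append((i, j, float(np.linalg.norm(coms[i] - coms[j]))))
    inter = [d for i, j, d in pairs
             if config.nanofoci[i].channel != config.nanofoci[j].channel]
    min_d = min(inter)
    max_d = max(d for _, _, d in pairs)
    return min_d, max_d, pairs


def assign_close_far(config: FocusConfiguration) -> dict[int, str]:
    """Close/far roles for the duplicated channel of a D2R1 or D1R2 focus.

    The duplicated-channel nanofocus realising the inter-channel minimum
    distance is *close*, the other *far*; the singleton channel nanofocus
    is *single*.  Ties are broken toward the larger-area nanofocus, then
    the lower index.
    """
    label = classify_dxry(config)
    if label not in ("D2R1", "D1R2"):
        raise ValueError(f"close/far roles are defined for D2R1/D1R2, not {label}")
    dup_ch = "DMC1" if label == "D2R1" else "RAD51"
    single_ch = "RAD51" if dup_ch == "DMC1" else "DMC1"
    (si, single) = config.by_channel(single_ch)[0]
    dup = config.by_channel(dup_ch)
    # sort key: distance to singleton, tie-break by larger area, lower index
    ranked = sorted(
        dup, key=lambda item: (
            float(np.linalg.norm(item[1].com_nm - single.com_nm)),
            -item[1].area_px, item[0]))
    roles = {si: "single", ranked[0][0]: "close", ranked[1][0]: "far"}
    return roles


def _mask_eccentricity(nf: Nanofocus) -> float:
    props = regionprops(nf.mask.astype(np.uint8))
    return float(props[0].eccentricity) if props else 0.0


def _overlap_edges(config: FocusConfiguration) -> list[tuple[int, int]]:
    """Inter-channel nanofocus pairs whose masks share at least one pixel."""
    edges = []
    for i, a in enumerate(config.nanofoci):
        for j in range(i + 1, len(config.nanofoci)):
            b = config.nanofoci[j]
            if a.channel == b.channel:
                continue
            if a.mask.shape == b.mask.shape and (a.mask & b.mask).any():
                edges.append((i, j))
    return edges


def classify_morphology(
    config: FocusConfiguration,
    major_fraction: float = 0.5,
    eccentricity_max: float = 0.85,
) -> str:
    """Deterministic morphology class from the mask-overlap graph.

    Nanofoci are nodes; an edge joins an inter-channel pair whose 5 nm
    binary masks share at least one pixel.  A nanofocus is *major* when
    its area reaches ``major_fraction`` of the largest same-channel
    nanofocus, *satellite* otherwise.  Classes, in precedence order:

    * ``bridge_D2R1`` / ``bridge_D1R2`` -- one RAD51 (resp. DMC1)
      nanofocus overlapping two or more of the other channel, i.e. a
      DMC1-RAD51-DMC1 (RAD51-DMC1-RAD51) connected chain;
    * ``paired`` -- two disjoint overlapping DMC1-RAD51 twin pairs;
    * ``simple`` -- the largest DMC1 and RAD51 nanofoci overlap, both are
      roundish (mask eccentricity <= ``eccentricity_max``) and every other
      nanofocus is a separate small satellite;
    * ``complex`` -- as simple but failing the roundness or
      satellite-size criteria;
    * ``separate`` -- no inter-channel overlap at all;
    * ``unclassified`` -- anything else (never produced by the above for
      foci with at least one nanofocus per channel, kept as a total-rule
      fallback).

    The thresholds are explicit, configurable proxies for what was a
    manual visual classification.
    """
    if not config.nanofoci:
        return "unclassified"
    edges = _overlap_edges(config)
    if not edges:
        return "separate"
    # bridge: a node connected to >= 2 nanofoci of the other channel
    degree: dict[int, int] = {}
    for i, j in edges:
        degree[i] = degree.get(i, 0) + 1
        degree[j] = degree.get(j, 0) + 1
    bridges = [i for i, d in degree.items() if d >= 2]
    if bridges:
        # highest-degree bridging node decides the orientation
        node = max(bridges, key=lambda i: (degree[i], config.nanofoci[i].area_px))
        return ("bridge_D2R1" if config.nanofoci[node].channel == "RAD51"
                else "bridge_D1R2")
    # all nodes now have degree 1: edges are disjoint D-R twin pairs
    if len(edges) >= 2:
        return "paired"
    i, j = edges[0]
    majors = {}
    for ch in ("DMC1", "RAD51"):
        items = config.by_channel(ch)
        if not items:
            return "unclassified"
        amax = max(nf.area_px for _, nf in items)
        majors[ch] = {k for k, nf in items
                      if nf.area_px >= major_fraction * amax}
    pair_is_major = (i in majors[config.nanofoci[i].channel]
                     and j in majors[config.nanofoci[j].channel])
    if not pair_is_major:
        return "complex"
    satellites_small = all(
        k in (i, j) or k not in majors[nf.channel]
        for k, nf in enumerate(config.nanofoci))
    round_majors = (_mask_eccentricity(config.nanofoci[i]) <= eccentricity_max
                    and _mask_eccentricity(config.nanofoci[j]) <= eccentricity_max)
    return "simple" if (satellites_small and round_majors) else "complex"


def axis_min_distance(
    nanofocus: Nanofocus | np.ndarray,
    polylines: list[AxisPolyline],
    near_cutoff: float = AXIS_NEAR_CUTOFF,
) -> tuple[float, bool]:
    """Shortest distance from a nanofocus centre of mass to any axis.

    Accepts a :class:`Nanofocus` or a bare (x, y) point in nm.  Returns
    ``(distance_nm, near)`` where ``near`` is False for distances beyond
    ``near_cutoff`` (1 um): such nanofoci are considered not on an axis.
    """
    if not polylines:
        raise ValueError("no axis polylines supplied")
    p = (nanofocus.com_nm if isinstance(nanofocus, Nanofocus)
         else np.asarray(nanofocus, dtype=float).reshape(2))
    best = np.inf
    for axis in polylines:
        pts = axis.points
        a, b = pts[:-1], pts[1:]
        ab = b - a
        denom = (ab**2).sum(axis=1)
        denom[denom == 0] = 1.0
        t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1).min()
        best = min(best, float(d))
    return best, best <= near_cutoff


def analyze_configuration(
    roi_id: str,
    nanofoci: list[Nanofocus],
    stage: str = "",
    synapsed: bool | None = None,
    major_fraction: float = 0.5,
    eccentricity_max: float = 0.85,
) -> FocusConfiguration:
    """Assemble the full configuration record for one segmented focus.

    Distances and roles are filled in where defined (both channels
    present; D2R1/D1R2 for roles); otherwise they stay ``None``/empty.
    """
    config = FocusConfiguration(roi_id=roi_id, nanofoci=list(nanofoci),
                                stage=stage, synapsed=synapsed)
    config.label = classify_dxry(config)
    if config.n_D >= 1 and config.n_R >= 1:
        config.min_dist, config.max_dist, _ = inter_channel_distances(config)
        if config.label in ("D2R1", "D1R2"):
            config.roles = assign_close_far(config)
    if config.nanofoci:
        config.morphology = classify_morphology(
            config, major_fraction=major_fraction,
            eccentricity_max=eccentricity_max)
    return config
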