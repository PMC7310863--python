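"""Rotational alignment of foci to a common frame and consensus analysis.

To reveal consensus patterns hidden by the random in-plane orientation of
individual foci, each focus is translated so that an *anchor* nanofocus
centre sits at the origin and rotated (rigid motion, determinant +1, no
reflection) so that a *goal* nanofocus centre lies on the positive y axis.
Localisations pooled over many aligned foci are rendered as summed
consensus images, quantified by quadrant occupancy, and profiled by a 1D
Gaussian fit along the alignment axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from nanofoci.foci_class import FocusConfiguration
from nanofoci.nanoseg import RoiRecord

QUADRANTS = ("top", "bottom", "left", "right")


def rotate_align(
    events_xy: np.ndarray,
    anchor_centre: np.ndarray,
    goal_centre: np.ndarray,
) -> np.ndarray:
    """Rigid motion sending anchor to the origin and goal onto +y.

    Translation by ``-anchor`` followed by the proper rotation that maps
    the anchor-to-goal direction onto (0, 1).  All pairwise distances and
    chirality are preserved.
    """
    anchor = np.asarray(anchor_centre, dtype=float).reshape(2)
    goal = np.asarray(goal_centre, dtype=float).reshape(2)
    v = goal - anchor
    d = np.linalg.norm(v)
    if d < 1e-12:
        raise ValueError("anchor and goal centres coincide")
    # rotation by (pi/2 - angle(v)) maps v/|v| onto (0, 1)
    c, s = v[1] / d, v[0] / d
    rot = np.array([[c, -s], [s, c]])
    pts = np.asarray(events_xy, dtype=float).reshape(-1, 2)
    return (pts - anchor) @ rot.T


@dataclass
class AlignedStack:
    """Pooled localisations of many foci in the common rotated frame."""

    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["x_nm", "y_nm", "channel", "roi_id"]))
    stage: str = ""
    anchor: str = ""
    goal: str = ""
    goal_distances: dict[str, float] = field(default_factory=dict)

    @property
    def n_foci(self) -> int:
        return self.events["roi_id"].nunique() if len(self.events) else 0

    def channel_xy(self, channel: str) -> np.ndarray:
        sel = self.events[self.events["channel"] == channel]
        return sel[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def add(self, roi_id: str, events: pd.DataFrame, goal_distance: float) -> None:
        sub = events[["x_nm", "y_nm", "channel"]].copy()
        sub["roi_id"] = roi_id
        self.events = (sub if not len(self.events)
                       else pd.concat([self.events, sub], ignore_index=True))
        self.goal_distances[roi_id] = goal_distance


def align_focus(
    roi: RoiRecord,
    config: FocusConfiguration,
    anchor: str,
    goal: str,
) -> tuple[pd.DataFrame, float]:
    """Align one focus by its nanofocus roles.

    ``anchor`` and ``goal`` name nanofocus roles: ``close``, ``far`` or
    ``single`` for D2R1/D1R2 configurations, or the channel names
    ``DMC1``/``RAD51`` for D1R1 foci.  Returns the rotated event table
    and the anchor-goal distance.
    """
    def centre(name: str) -> np.ndarray:
        nf = config.role_nanofocus(name)
        if nf is None:
            items = config.by_channel(name)
            if len(items) != 1:
                raise ValueError(
                    f"focus {config.roi_id}: cannot resolve '{name}' "
                    f"to a unique nanofocus")
            nf = items[0][1]
        return nf.com_nm

    a, g = centre(anchor), centre(goal)
    rotated = rotate_align(
        roi.events[["x_nm", "y_nm"]].to_numpy(dtype=float), a, g)
    out = roi.events.copy()
    out["x_nm"] = rotated[:, 0]
    out["y_nm"] = rotated[:, 1]
    return out, float(np.linalg.norm(g - a))


def build_stack(
    rois: list[RoiRecord],
    configs: list[FocusConfiguration],
    anchor: str,
    goal: str,
    stage: str = "",
) -> AlignedStack:
    """Pool the aligned localisations of all foci that carry the roles."""
    stack = AlignedStack(stage=stage, anchor=anchor, goal=goal)
    for roi, config in zip(rois, configs):
        try:
            events, dist = align_focus(roi, config, anchor, goal)
        except ValueError:
            continue
        stack.add(config.roi_id, events, dist)
    return stack


def pool_and_render(
    stack: AlignedStack,
    pixel: float = 5.0,
    extent: float | None = None,
) -> dict[str, np.ndarray]:
    """Summed consensus image per channel on a common origin-centred grid.

    Events are binned on a square grid centred on the origin (the anchor
    position).  ``extent`` is the half-width in nm; by default the grid
    covers all pooled events, so the total rendered mass equals the
    pooled event count.  Pooling order cannot affect the sum.
    """
    if not len(stack.events):
        raise ValueError("cannot render an empty stack")
    xy = stack.events[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if extent is None:
        extent = float(np.abs(xy).max()) + pixel
    n = int(np.ceil(2 * extent / pixel))
    edges = np.linspace(-extent, extent, n + 1)
    out = {}
    for ch in stack.events["channel"].unique():
        cxy = stack.channel_xy(ch)
        img, _, _ = np.histogram2d(cxy[:, 1], cxy[:, 0], bins=(edges, edges))
        out[str(ch)] = img
    return out


def quadrant_fractions(stack: AlignedStack, channel: str) -> dict[str, float]:
    """Fraction of a channel's events in the four 90-degree wedges.

    The plane is split by the lines y = x and y = -x into wedges centred
    on the +y (top), -y (bottom), -x (left) and +x (right) half-axes, so
    "top" is bisected by the alignment direction.  Boundary events with
    |x| = |y| count toward the vertical wedges; the fractions always sum
    to one.
    """
    xy = stack.channel_xy(channel)
    if len(xy) == 0:
        raise ValueError(f"stack has no events in channel {channel}")
    x, y = xy[:, 0], xy[:, 1]
    top = y >= np.abs(x)
    bottom = (-y >= np.abs(x)) & ~top
    left = (np.abs(x) > np.abs(y)) & (x < 0)
    right = (np.abs(x) > np.abs(y)) & (x > 0)
    n = len(xy)
    return {
        "top": float(top.sum()) / n,
        "bottom": float(bottom.sum()) / n,
        "left": float(left.sum()) / n,
        "right": float(right.sum()) / n,
    }


def top_half_fraction(stack: AlignedStack, channel: str) -> float:
    """Fraction of a channel's events above the anchor centre (y > 0)."""
    xy = stack.channel_xy(channel)
    if len(xy) == 0:
        raise ValueError(f"stack has no events in channel {channel}")
    return float((xy[:, 1] > 0).mean())


def fit_sigma(
    stack: AlignedStack,
    channel: str,
    bin_width: float = 5.0,
    min_events: int = 50,
) -> tuple[float, float]:
    """Gaussian width of a channel's profile along the alignment axis.

    A single Gaussian with constant offset is least-squares fitted to the
    histogram of the pooled y coordinates; returns ``(sigma, fwhm)`` with
    FWHM = 2*sqrt(2*ln 2)*sigma (approximately 2.355 sigma).  Degenerate
    input (all events coincident) yields sigma 0 with a warning.
    """
    y = stack.channel_xy(channel)[:, 1]
    if len(y) < min_events:
        raise ValueError(f"need >= {min_events} events to fit, got {len(y)}")
    if np.ptp(y) < 1e-9:
        import warnings
        warnings.warn("all events coincident along the alignment axis; sigma = 0")
        return 0.0, 0.0
    lo, hi = y.min() - bin_width, y.max() + bin_width
    n_bins = max(5, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(y, bins=n_bins, range=(lo, hi))
    centres = 0.5 * (edges[:-1] + edges[1:])

    def gauss(t, amp, mu, sig, off):
        return amp * np.exp(-0.5 * ((t - mu) / sig) ** 2) + off

    p0 = (counts.max(), float(np.mean(y)), float(np.std(y)), 0.0)
    popt, _ = curve_fit(gauss, centres, counts, p0=p0, maxfev=20000)
    sigma = abs(float(popt[2]))
    fwhm = 2 * np.sqrt(2 * np.log(2)) * sigma
    return sigma, fwhm


_PAIR_ROLES = {
    "D1R1": [("DMC1", "RAD51", "D-R")],
    "D2R1": [("close", "single", "closeD-R"), ("far", "single", "farD-R"),
             ("close", "far", "D-D")],
    "D1R2": [("close", "single", "closeR-D"), ("far", "single", "farR-D"),
             ("close", "far", "R-R")],
}


def stack_distances(
    configs_by_stage: dict[str, list[FocusConfiguration]],
) -> pd.DataFrame:
    """Mean and SEM of the named nanofocus-pair distances per stage.

    For D2R1 (D1R2) foci the close-to-singleton, far-to-singleton and
    duplicated-channel pair distances are summarised; for D1R1 the single
    DMC1-RAD51 distance.  SEM uses the n-1 convention and is 0 for a
    single focus.
    """
    rows = []
    for stage, configs in configs_by_stage.items():
        samples: dict[str, list[float]] = {}
        for config in configs:
            pair_spec = _PAIR_ROLES.get(config.label)
            if pair_spec is None:
                continue
            for role_a, role_b, name in pair_spec:
                try:
                    if config.label == "D1R1":
                        a = config.by_channel(role_a)[0][1].com_nm
                        b = config.by_channel(role_b)[0][1].com_nm
                    else:
                        a = config.role_nanofocus(role_a).com_nm
                        b = config.role_nanofocus(role_b).com_nm
                except (AttributeError, IndexError):
                    continue
                samples.setdefault((config.label, name), []).append(
                    float(np.linalg.norm(a - b)))
        for (label, name), vals in samples.items():
            v = np.asarray(vals)
            sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
            rows.append({
                "stage": stage, "configuration": label, "pair": name,
                "mean_nm": float(v.mean()), "sem_nm": sem, "n": len(v),
            })
    return pd.DataFrame(rows, columns=[
        "stage", "configuration", "pair", "mean_nm", "sem_nm", "n"])
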