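"""Synthetic localisation data and confocal-like image generation.

Two generators are provided.  :func:`gen_d2r1_focus` realises the 3D
generative model of a D2R1 repair focus: two globular DMC1 localisation
clusters 400 nm apart plus one ellipsoidal RAD51 cluster attached to the
close DMC1 cluster at a bounded random angle to the DMC1--DMC1 axis.
:func:`gen_nucleus_localizations` builds whole-nucleus localisation tables
with Gaussian focus clusters placed on curvilinear chromosome-axis
polylines, and :func:`render_confocal` turns point patterns into
diffraction-blurred, shot-noise-corrupted confocal-like images.

All randomness flows through an explicit :class:`numpy.random.Generator`;
per-focus substreams are spawned from it so outputs are reproducible
bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

DMC1 = "DMC1"
RAD51 = "RAD51"


@dataclass
class D2R1Model:
    """Parameters of the generative 3D model of a D2R1 repair focus.

    The model consists of three Gaussian clusters of 3D coordinates: a
    globular *close* DMC1 cluster, a globular *far* DMC1 cluster whose
    centre sits at ``d_far`` (default 400 nm) from the close centre in a
    uniformly random 3D direction, and an ellipsoidal RAD51 cluster
    physically attached to the close DMC1 cluster.  The RAD51 major axis
    makes an angle with the close-to-far DMC1 axis drawn uniformly in
    ``[0, alpha_max]`` with uniformly random azimuth; its centre is offset
    from the close DMC1 centre by ``attach_offset_factor * sigma_R_major``
    along that axis, so the filament emanates from the close cluster.
    Uniform background localisations fill a cube of side ``bg_extent``
    centred on the close DMC1 cluster.

    Localisation counts default to the mean number of localisations
    measured per nanofocus in the source dataset: 267 RAD51, 564 close
    DMC1 and 51 far DMC1 coordinates, plus 50 background coordinates.

    The cluster standard deviations of the DMC1 nanofoci are not fixed by
    the experimental summaries; defaults (30 nm close, 15 nm far)
    place the segmented nanofocus areas in the observed large/small
    regime, with the small far nanofocus roughly an order of magnitude
    smaller in area than the close one.  ``sigma_R_minor`` defaults to
    ``sigma_D_far`` (only the major axis is varied when fitting).
    """

    sigma_R_major: float = 144.0 / 2.355  # nm; pachytene best-fit FWHM 144 nm
    alpha_max: float = 105.0              # degrees
    sigma_R_minor: float | None = None    # nm; None -> sigma_D_far
    sigma_D_close: float = 30.0           # nm
    sigma_D_far: float = 15.0             # nm
    n_R: int = 267
    n_D_close: int = 564
    n_D_far: int = 51
    n_bg: int = 50
    d_far: float = 400.0                  # nm
    bg_extent: float = 600.0              # nm, cube side
    attach_offset_factor: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def minor_sigma(self) -> float:
        return self.sigma_D_far if self.sigma_R_minor is None else self.sigma_R_minor

    @property
    def fwhm_R(self) -> float:
        """Full width at half maximum of the RAD51 major axis (2.355 sigma)."""
        return 2 * np.sqrt(2 * np.log(2)) * self.sigma_R_major

    def validate(self) -> None:
        sigmas = (self.sigma_R_major, self.sigma_D_close, self.sigma_D_far,
                  self.minor_sigma)
        if any(s <= 0 for s in sigmas):
            raise ValueError("all cluster standard deviations must be > 0")
        if not 0.0 <= self.alpha_max <= 180.0:
            raise ValueError("alpha_max must lie in [0, 180] degrees")
        counts = (self.n_R, self.n_D_close, self.n_D_far, self.n_bg)
        if any(c < 0 for c in counts):
            raise ValueError("localisation counts must be >= 0")
        if self.d_far <= 0:
            raise ValueError("d_far must be > 0")
        if self.bg_extent <= 0:
            raise ValueError("bg_extent must be > 0")


class SimulatedFocus(NamedTuple):
    """Localisation table of one simulated focus plus its ground truth."""

    points: pd.DataFrame  # columns x_nm, y_nm, z_nm, channel, cluster
    truth: dict


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability zero in practice
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _rotation_from_x(u: np.ndarray) -> np.ndarray:
    """Rotation matrix sending the x unit vector onto unit vector ``u``."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, u)
    c = float(np.dot(x, u))
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def gen_d2r1_focus(model: D2R1Model, rng: np.random.Generator) -> SimulatedFocus:
    """Simulate one 3D D2R1 focus.

    Returns a :class:`SimulatedFocus` whose ``points`` table holds exactly
    ``n_R + n_D_close + n_D_far`` channel-labelled localisations plus
    ``n_bg`` background localisations (``cluster == "background"``;
    background points are assigned a channel uniformly at random, since
    spurious detections occur in both colour channels).  ``truth`` records
    the cluster centres and the RAD51 axis direction.
    """
    model.validate()
    close_c = np.zeros(3)
    far_dir = _random_unit_vector(rng)
    far_c = model.d_far * far_dir

    # RAD51 major axis: polar angle uniform in [0, alpha_max] from the
    # close->far DMC1 axis, azimuth uniform around it.
    theta = np.deg2rad(rng.uniform(0.0, model.alpha_max)) if model.alpha_max > 0 else 0.0
    a = np.array([1.0, 0, 0]) if abs(far_dir[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(far_dir, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(far_dir, e1)
    phi = rng.uniform(0.0, 2 * np.pi)
    u = (np.cos(theta) * far_dir
         + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
    rad51_c = close_c + model.attach_offset_factor * model.sigma_R_major * u

    d_close = close_c + rng.normal(scale=model.sigma_D_close,
                                   size=(model.n_D_close, 3))
    d_far = far_c + rng.normal(scale=model.sigma_D_far, size=(model.n_D_far, 3))
    ell = rng.normal(size=(model.n_R, 3)) * np.array(
        [model.sigma_R_major, model.minor_sigma, model.minor_sigma])
    rad51 = rad51_c + ell @ _rotation_from_x(u).T

    bg = rng.uniform(-model.bg_extent / 2, model.bg_extent / 2,
                     size=(model.n_bg, 3)) + close_c
    bg_channel = rng.integers(0, 2, size=model.n_bg)

    xyz = np.vstack([d_close, d_far, rad51, bg])
    channel = np.concatenate([
        np.repeat(DMC1, model.n_D_close + model.n_D_far),
        np.repeat(RAD51, model.n_R),
        np.where(bg_channel == 0, DMC1, RAD51),
    ])
    cluster = np.concatenate([
        np.repeat("close_dmc1", model.n_D_close),
        np.repeat("far_dmc1", model.n_D_far),
        np.repeat("rad51", model.n_R),
        np.repeat("background", model.n_bg),
    ])
    points = pd.DataFrame({
        "x_nm": xyz[:, 0], "y_nm": xyz[:, 1], "z_nm": xyz[:, 2],
        "channel": channel, "cluster": cluster,
    })
    truth = {
        "close_dmc1": close_c,
        "far_dmc1": far_c,
        "rad51": rad51_c,
        "rad51_axis": u,
        "theta_deg": float(np.rad2deg(theta)),
    }
    return SimulatedFocus(points, truth)


# ---------------------------------------------------------------------------
# Whole-nucleus layouts


@dataclass
class ClusterSpec:
    """One Gaussian localisation cluster within a focus."""

    channel: str
    n: int
    sigma: float                        # nm, isotropic in-plane SD
    offset: tuple[float, float] = (0.0, 0.0)  # nm, relative to focus position


@dataclass
class FocusSpec:
    """A focus pinned to an axis polyline at a given arc-length position."""

    axis: int          # index into NucleusLayout.axis_polylines
    arclength: float   # nm along the polyline
    clusters: list[ClusterSpec] = field(default_factory=list)


@dataclass
class NucleusLayout:
    """Synthetic stand-in for a spread nucleus: axes plus focus positions."""

    axis_polylines: list[np.ndarray]       # each (k, 2) in nm
    focus_specs: list[FocusSpec]
    field_size: tuple[float, float] = (20000.0, 20000.0)  # nm

    def validate(self) -> None:
        w, h = self.field_size
        for poly in self.axis_polylines:
            p = np.asarray(poly, dtype=float)
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
                raise ValueError("each axis polyline needs >= 2 2D points")
            if (p < 0).any() or (p[:, 0] > w).any() or (p[:, 1] > h).any():
                raise ValueError("axis polyline leaves the field bounds")
        for spec in self.focus_specs:
            if not 0 <= spec.axis < len(self.axis_polylines):
                raise ValueError(f"focus references missing axis {spec.axis}")


def point_on_polyline(poly: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length ``s`` along a polyline (clamped to its ends)."""
    p = np.asarray(poly, dtype=float)
    seg = np.diff(p, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = 0.0 if seg_len[i] == 0 else (s - cum[i]) / seg_len[i]
    return p[i] + t * seg[i]


def gen_nucleus_localizations(
    layout: NucleusLayout, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realise a layout as a localisation table plus its ground truth.

    Returns ``(table, truth)`` where ``table`` has columns
    ``x_nm, y_nm, channel, focus_id`` and ``truth`` one row per cluster
    with the true centre and intended count.  Each focus draws from its
    own substream so inserting or removing foci does not perturb the
    coordinates of the others.
    """
    layout.validate()
    rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    substreams = rng.spawn(len(layout.focus_specs))
    for fid, (spec, sub) in enumerate(zip(layout.focus_specs, substreams)):
        base = point_on_polyline(layout.axis_polylines[spec.axis], spec.arclength)
        for ci, cl in enumerate(spec.clusters):
            centre = base + np.asarray(cl.offset, dtype=float)
            xy = centre + sub.normal(scale=cl.sigma, size=(cl.n, 2))
            rows.append(pd.DataFrame({
                "x_nm": xy[:, 0], "y_nm": xy[:, 1],
                "channel": cl.channel, "focus_id": fid,
            }))
            truth_rows.append({
                "focus_id": fid, "cluster": ci, "channel": cl.channel,
                "x_nm": centre[0], "y_nm": centre[1],
                "sigma": cl.sigma, "n": cl.n,
            })
    if not rows:
        table = pd.DataFrame(columns=["x_nm", "y_nm", "channel", "focus_id"])
    else:
        table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=[
        "focus_id", "cluster", "channel", "x_nm", "y_nm", "sigma", "n"])
    return table, truth


def sine_axis_layout(
    n_foci: int,
    n_axes: int = 3,
    field: float = 20000.0,
    locs_per_channel: int = 1500,
    cluster_sigma: float = 15.0,
    pair_offset: float = 70.0,
    rng: np.random.Generator | None = None,
) -> NucleusLayout:
    """Convenience layout: gently curved axes with paired DMC1/RAD51 foci.

    Each focus carries one DMC1 and one RAD51 cluster ``pair_offset`` nm
    apart, mimicking the predominant partially-overlapping configuration.
    Cluster counts default to a regime where both channels are robustly
    segmentable at the standard density threshold.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    margin = 0.1 * field
    xs = np.linspace(margin, field - margin, 40)
    polys = []
    for i in range(n_axes):
        y0 = field * (i + 1) / (n_axes + 1)
        amp = 0.05 * field
        ys = y0 + amp * np.sin(2 * np.pi * xs / field + i)
        polys.append(np.column_stack([xs, ys]))
    total_len = sum(
        np.hypot(*np.diff(p, axis=0).T).sum() for p in polys)
    specs = []
    for k in range(n_foci):
        ax = k % n_axes
        plen = np.hypot(*np.diff(polys[ax], axis=0).T).sum()
        # spread foci evenly with a jitter, keeping them well separated
        s = (k // n_axes + 0.5) / max(1, -(-n_foci // n_axes)) * plen
        s += rng.uniform(-0.01, 0.01) * plen
        ang = rng.uniform(0, 2 * np.pi)
        off = pair_offset * np.array([np.cos(ang), np.sin(ang)])
        specs.append(FocusSpec(ax, float(s), [
            ClusterSpec(DMC1, locs_per_channel, cluster_sigma, (0.0, 0.0)),
            ClusterSpec(RAD51, locs_per_channel, cluster_sigma,
                        (float(off[0]), float(off[1]))),
        ]))
    del total_len
    return NucleusLayout(polys, specs, (field, field))


# ---------------------------------------------------------------------------
# Confocal-like rendering


@dataclass
class ConfocalRenderParams:
    """Rendering parameters for diffraction-blurred confocal-like images.

    ``blur_sigma`` is the standard deviation of the Gaussian point-spread
    approximation, 110 nm (0.11 um) by default; ``blur_sigma_um`` may be
    given instead and is converted to nm.  ``base_offset`` (5 intensity
    units) and the per-pixel uniform noise in +/- sqrt(intensity) emulate
    camera offset and shot noise.  ``focus_amplitude`` is the pre-blur
    single-pixel impulse value; the default 1000 yields a blurred peak of
    ~129 above offset at 99 nm pixels, comfortably above the 90/100
    detection noise tolerances.
    """

    pixel_size: float = 99.0       # nm
    blur_sigma: float = 110.0      # nm
    base_offset: float = 5.0
    focus_amplitude: float = 1000.0
    blur_sigma_um: float | None = None

    def __post_init__(self) -> None:
        if self.blur_sigma_um is not None:
            self.blur_sigma = 1000.0 * self.blur_sigma_um
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be > 0")


def render_confocal(
    points_nm: np.ndarray,
    params: ConfocalRenderParams,
    rng: np.random.Generator | None,
    shape: tuple[int, int],
) -> np.ndarray:
    """Render 2D points as a blurred, noisy confocal-like image.

    Single-pixel impulses of value ``focus_amplitude`` are placed at the
    point positions, blurred with a Gaussian of ``blur_sigma``, offset by
    ``base_offset``, and corrupted with per-pixel uniform noise in
    +/- sqrt(intensity).  Pass ``rng=None`` for a noise-free rendering.

    ``shape`` is (rows, cols); points are (x, y) in nm and must fall
    inside the field.
    """
    pts = np.asarray(points_nm, dtype=float).reshape(-1, 2)
    ny, nx = shape
    img = np.zeros(shape, dtype=float)
    if len(pts):
        px = params.pixel_size
        ix = np.floor(pts[:, 0] / px).astype(int)
        iy = np.floor(pts[:, 1] / px).astype(int)
        if (ix < 0).any() or (iy < 0).any() or (ix >= nx).any() or (iy >= ny).any():
            raise ValueError("points fall outside the image field")
        np.add.at(img, (iy, ix), params.focus_amplitude)
        img = gaussian_filter(img, sigma=params.blur_sigma / px, mode="constant")
    img += params.base_offset
    if rng is not None:
        img += rng.uniform(-1.0, 1.0, size=img.shape) * np.sqrt(np.abs(img))
    return img
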