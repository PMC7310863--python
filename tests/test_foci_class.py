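"""DxRy labels, inter-nanofocus distances, roles, morphology, axis distances."""

import numpy as np
import pytest

from nanofoci.foci_class import (
    AxisPolyline, FocusConfiguration, analyze_configuration, assign_close_far,
    axis_min_distance, classify_dxry, classify_morphology, collapse_label,
    inter_channel_distances,
)
from nanofoci.nanoseg import Nanofocus

from conftest import make_nanofocus


def config_from(nanofoci, roi_id="t"):
    c = FocusConfiguration(roi_id=roi_id, nanofoci=list(nanofoci))
    c.label = classify_dxry(c)
    return c


def mask_nf(channel, cols, rows, com=None, grid=(60, 60)):
    """Nanofocus with an explicit rectangular mask on a shared 5 nm grid."""
    mask = np.zeros(grid, dtype=bool)
    mask[rows[0]:rows[1], cols[0]:cols[1]] = True
    if com is None:
        com = (5.0 * (cols[0] + cols[1]) / 2, 5.0 * (rows[0] + rows[1]) / 2)
    return Nanofocus(channel=channel, mask=mask, pixel_size=5.0,
                     origin=np.zeros(2), area_px=int(mask.sum()),
                     com_nm=np.asarray(com, dtype=float), n_locs=100)


class TestDxRy:
    def test_labels_and_collapse(self):
        c = config_from([make_nanofocus("DMC1", (0, 0)),
                         make_nanofocus("DMC1", (0, 300)),
                         make_nanofocus("RAD51", (0, 60))])
        assert c.label == "D2R1"
        assert collapse_label("D2R1") == "D2R1"
        assert classify_dxry(config_from([])) == "D0R0"
        many = config_from([make_nanofocus("DMC1", (i * 200, 0))
                            for i in range(3)]
                           + [make_nanofocus("RAD51", (i * 200, 300))
                              for i in range(2)])
        assert many.label == "D3R2"
        assert collapse_label(many.label) == "rest"


class TestDistances:
    def test_d1r1_min_equals_max(self):
        c = config_from([make_nanofocus("DMC1", (0, 0)),
                         make_nanofocus("RAD51", (0, 70))])
        mn, mx, _ = inter_channel_distances(c)
        assert mn == mx == pytest.approx(70.0)

    def test_hand_geometry_d2r1(self):
        """Min is R-to-close-D (60); max is the D-D pair (300)."""
        c = config_from([make_nanofocus("DMC1", (0, 0)),
                         make_nanofocus("DMC1", (0, 300)),
                         make_nanofocus("RAD51", (0, 60))])
        mn, mx, _ = inter_channel_distances(c)
        assert mn == pytest.approx(60.0)
        assert mx == pytest.approx(300.0)

    def test_brute_force_random_roi(self, rng):
        coms = rng.uniform(0, 500, size=(4, 2))
        chans = ["DMC1", "DMC1", "RAD51", "RAD51"]
        c = config_from([make_nanofocus(ch, com)
                         for ch, com in zip(chans, coms)])
        mn, mx, pairs = inter_channel_distances(c)
        dist = {(i, j): np.linalg.norm(coms[i] - coms[j])
                for i in range(4) for j in range(i + 1, 4)}
        inter = [d for (i, j), d in dist.items() if chans[i] != chans[j]]
        assert mn == pytest.approx(min(inter))
        assert mx == pytest.approx(max(dist.values()))
        assert len(pairs) == 6
        assert mn <= mx

    def test_missing_channel_raises(self):
        c = config_from([make_nanofocus("DMC1", (0, 0))])
        with pytest.raises(ValueError, match="undefined"):
            inter_channel_distances(c)

    @pytest.mark.parametrize("seed", range(5))
    def test_min_le_max_property(self, seed):
        rng = np.random.default_rng(seed)
        n_d, n_r = rng.integers(1, 4, size=2)
        nfs = ([make_nanofocus("DMC1", rng.uniform(0, 600, 2))
                for _ in range(n_d)]
               + [make_nanofocus("RAD51", rng.uniform(0, 600, 2))
                  for _ in range(n_r)])
        mn, mx, _ = inter_channel_distances(config_from(nfs))
        assert mn <= mx + 1e-12


class TestCloseFar:
    def test_roles_from_min_rule(self):
        c = config_from([make_nanofocus("DMC1", (0, 0)),
                         make_nanofocus("DMC1", (0, 300)),
                         make_nanofocus("RAD51", (0, 60))])
        roles = assign_close_far(c)
        assert roles == {2: "single", 0: "close", 1: "far"}

    def test_tie_break_larger_area_is_close(self):
        c = config_from([make_nanofocus("DMC1", (0, 200), area_px=30),
                         make_nanofocus("DMC1", (0, -200), area_px=90),
                         make_nanofocus("RAD51", (0, 0))])
        roles = assign_close_far(c)
        assert roles[1] == "close" and roles[0] == "far"

    def test_d1r2_mirror(self):
        c = config_from([make_nanofocus("RAD51", (0, 0)),
                         make_nanofocus("RAD51", (0, 300)),
                         make_nanofocus("DMC1", (0, 60))])
        roles = assign_close_far(c)
        assert roles == {2: "single", 0: "close", 1: "far"}

    def test_other_labels_raise(self):
        c = config_from([make_nanofocus("DMC1", (0, 0)),
                         make_nanofocus("RAD51", (0, 70))])
        with pytest.raises(ValueError):
            assign_close_far(c)


class TestMorphology:
    def test_bridge_d2r1(self):
        """One RAD51 mask overlapping two DMC1 masks is a D2R1 bridge."""
        d1 = mask_nf("DMC1", (5, 15), (20, 30))
        d2 = mask_nf("DMC1", (35, 45), (20, 30))
        r = mask_nf("RAD51", (12, 38), (22, 28))
        assert classify_morphology(config_from([d1, d2, r])) == "bridge_D2R1"

    def test_bridge_d1r2(self):
        r1 = mask_nf("RAD51", (5, 15), (20, 30))
        r2 = mask_nf("RAD51", (35, 45), (20, 30))
        d = mask_nf("DMC1", (12, 38), (22, 28))
        assert classify_morphology(config_from([r1, r2, d])) == "bridge_D1R2"

    def test_separate(self):
        d = mask_nf("DMC1", (5, 15), (5, 15))
        r = mask_nf("RAD51", (35, 45), (35, 45))
        assert classify_morphology(config_from([d, r])) == "separate"

    def test_paired(self):
        """Two disjoint overlapping D-R twin pairs."""
        d1 = mask_nf("DMC1", (5, 15), (5, 15))
        r1 = mask_nf("RAD51", (10, 20), (5, 15))
        d2 = mask_nf("DMC1", (35, 45), (35, 45))
        r2 = mask_nf("RAD51", (40, 50), (35, 45))
        assert classify_morphology(config_from([d1, r1, d2, r2])) == "paired"

    def test_simple_round_overlapping_majors(self):
        d = mask_nf("DMC1", (10, 22), (10, 22))
        r = mask_nf("RAD51", (16, 28), (10, 22))
        assert classify_morphology(config_from([d, r])) == "simple"

    def test_simple_with_small_separate_satellite(self):
        d = mask_nf("DMC1", (10, 22), (10, 22))
        r = mask_nf("RAD51", (16, 28), (10, 22))
        sat = mask_nf("DMC1", (45, 48), (45, 48))  # 9 px satellite
        assert classify_morphology(config_from([d, r, sat])) == "simple"

    def test_elongated_major_is_complex(self):
        d = mask_nf("DMC1", (5, 45), (18, 22))    # 200x20 nm: eccentric
        r = mask_nf("RAD51", (20, 32), (16, 28))
        assert classify_morphology(config_from([d, r])) == "complex"

    def test_every_config_receives_one_class(self, rng):
        """Morphology is total over random segmented configurations."""
        from nanofoci.foci_class import MORPHOLOGIES
        for _ in range(20):
            nfs = []
            for _ in range(rng.integers(1, 5)):
                ch = "DMC1" if rng.random() < 0.5 else "RAD51"
                c0, r0 = rng.integers(0, 48, size=2)
                nfs.append(mask_nf(ch, (c0, c0 + rng.integers(3, 12)),
                                   (r0, r0 + rng.integers(3, 12))))
            morph = classify_morphology(config_from(nfs))
            assert morph in MORPHOLOGIES


class TestAxisDistance:
    def test_on_line_and_perpendicular(self):
        axis = AxisPolyline(np.array([[0.0, 0.0], [10000.0, 0.0]]))
        d, near = axis_min_distance(np.array([5000.0, 0.0]), [axis])
        assert d == pytest.approx(0.0) and near
        d, near = axis_min_distance(np.array([5000.0, 500.0]), [axis])
        assert d == pytest.approx(500.0) and near

    def test_far_nanofocus_flagged(self):
        axis = AxisPolyline(np.array([[0.0, 0.0], [10000.0, 0.0]]))
        d, near = axis_min_distance(np.array([5000.0, 1200.0]), [axis])
        assert d == pytest.approx(1200.0) and not near

    def test_dense_sampling_oracle(self, rng):
        """Matches distance to 1e4 interpolated axis points within 1 nm."""
        pts = np.cumsum(rng.uniform(-300, 500, size=(8, 2)), axis=0)
        axis = AxisPolyline(pts)
        # dense resampling of every segment
        dense = np.vstack([
            a + t * (b - a)
            for a, b in zip(pts[:-1], pts[1:])
            for t in np.linspace(0, 1, 1500)[:, None]])
        for _ in range(10):
            p = rng.uniform(-500, 1500, size=2)
            d, _ = axis_min_distance(p, [axis])
            oracle = np.linalg.norm(dense - p, axis=1).min()
            assert abs(d - oracle) < 1.0

    def test_empty_polyline_set_raises(self):
        with pytest.raises(ValueError):
            axis_min_distance(np.zeros(2), [])


class TestAnalyzeConfiguration:
    def test_full_record(self):
        nfs = [make_nanofocus("DMC1", (0, 0)),
               make_nanofocus("DMC1", (0, 300)),
               make_nanofocus("RAD51", (0, 60))]
        c = analyze_configuration("roi1", nfs, stage="pachytene")
        assert c.label == "D2R1"
        assert c.min_dist == pytest.approx(60.0)
        assert c.max_dist == pytest.approx(300.0)
        assert set(c.roles.values()) == {"close", "far", "single"}
        assert c.morphology != ""

    def test_single_channel_focus(self):
        c = analyze_configuration("roi2", [make_nanofocus("DMC1", (0, 0))])
        assert c.label == "D1R0"
        assert c.min_dist is None and c.roles == {}
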