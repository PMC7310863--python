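"""Rotation alignment, consensus pooling, quadrant occupancy, profile fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanofoci.foci_class import analyze_configuration
from nanofoci.rotalign import (
    AlignedStack, build_stack, fit_sigma, pool_and_render,
    quadrant_fractions, rotate_align, stack_distances, top_half_fraction,
)

from conftest import make_nanofocus, make_roi


def stack_from(xy, channel="RAD51"):
    s = AlignedStack()
    s.add("f", pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1],
                             "channel": channel}), 100.0)
    return s


class TestRotateAlign:
    def test_goal_already_on_axis_is_identity(self, rng):
        events = rng.uniform(-100, 100, size=(50, 2))
        out = rotate_align(events, (0.0, 0.0), (0.0, 80.0))
        assert out == pytest.approx(events)

    def test_quarter_turn(self):
        out = rotate_align(np.array([[70.0, 0.0]]), (0.0, 0.0), (70.0, 0.0))
        assert out[0] == pytest.approx([0.0, 70.0], abs=1e-12)

    def test_goal_lands_on_positive_y(self, rng):
        anchor = rng.uniform(-500, 500, size=2)
        goal = rng.uniform(-500, 500, size=2)
        out = rotate_align(goal[None], anchor, goal)
        d = np.linalg.norm(goal - anchor)
        assert out[0] == pytest.approx([0.0, d], abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_isometry_and_chirality(self, seed):
        """Alignment is a proper rigid motion: distances and orientation kept."""
        rng = np.random.default_rng(seed)
        events = rng.uniform(-300, 300, size=(12, 2))
        anchor, goal = rng.uniform(-300, 300, size=(2, 2))
        if np.linalg.norm(goal - anchor) < 1e-6:
            return
        out = rotate_align(events, anchor, goal)
        d0 = np.linalg.norm(events[:, None] - events[None], axis=2)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=2)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)
        # signed area of the first triangle is preserved (det = +1)
        def signed(p):
            u, v = p[1] - p[0], p[2] - p[0]
            return u[0] * v[1] - u[1] * v[0]
        assert np.sign(signed(events[:3])) == np.sign(signed(out[:3]))

    def test_coincident_anchor_goal_raises(self):
        with pytest.raises(ValueError):
            rotate_align(np.zeros((1, 2)), (1.0, 1.0), (1.0, 1.0))


class TestPooling:
    def _stack(self, frames):
        s = AlignedStack()
        for i, xy in enumerate(frames):
            s.add(f"f{i}", pd.DataFrame({
                "x_nm": xy[:, 0], "y_nm": xy[:, 1], "channel": "RAD51"}), 1.0)
        return s

    def test_single_focus_consensus(self, rng):
        xy = rng.normal(scale=50, size=(500, 2))
        img = pool_and_render(self._stack([xy]), extent=300.0)["RAD51"]
        assert img.sum() == 500

    def test_two_identical_foci_double(self, rng):
        xy = rng.normal(scale=50, size=(500, 2))
        one = pool_and_render(self._stack([xy]), extent=300.0)["RAD51"]
        two = pool_and_render(self._stack([xy, xy]), extent=300.0)["RAD51"]
        assert np.array_equal(two, 2 * one)

    def test_pooling_order_invariance(self, rng):
        a = rng.normal(scale=40, size=(300, 2))
        b = rng.normal(scale=80, size=(200, 2))
        ab = pool_and_render(self._stack([a, b]), extent=400.0)["RAD51"]
        ba = pool_and_render(self._stack([b, a]), extent=400.0)["RAD51"]
        assert np.array_equal(ab, ba)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            pool_and_render(AlignedStack())


class TestQuadrants:
    def test_pure_top(self):
        q = quadrant_fractions(stack_from(np.array([[0.0, 100.0]])), "RAD51")
        assert q == {"top": 1.0, "bottom": 0.0, "left": 0.0, "right": 0.0}

    def test_partition_sums_to_one(self, rng):
        q = quadrant_fractions(
            stack_from(rng.normal(size=(1000, 2))), "RAD51")
        assert sum(q.values()) == pytest.approx(1.0)

    def test_boundary_goes_to_vertical_wedges(self):
        xy = np.array([[50.0, 50.0], [-50.0, -50.0]])
        q = quadrant_fractions(stack_from(xy), "RAD51")
        assert q["top"] == 0.5 and q["bottom"] == 0.5
        assert q["left"] == q["right"] == 0.0

    def test_isotropic_cloud_quarter_each(self):
        rng = np.random.default_rng(5)
        q = quadrant_fractions(
            stack_from(rng.normal(scale=100, size=(40000, 2))), "RAD51")
        for v in q.values():
            assert v == pytest.approx(0.25, abs=0.01)

    def test_rotation_before_alignment_is_normalised_away(self, rng):
        """Quadrant fractions are invariant under a global pre-rotation."""
        events = rng.normal(scale=60, size=(800, 2)) + [0.0, 120.0]
        anchor, goal = np.zeros(2), np.array([0.0, 200.0])
        q0 = quadrant_fractions(
            stack_from(rotate_align(events, anchor, goal)), "RAD51")
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        q1 = quadrant_fractions(
            stack_from(rotate_align(events @ rot.T, anchor, rot @ goal)),
            "RAD51")
        for k in q0:
            assert q0[k] == pytest.approx(q1[k], abs=1e-12)

    def test_zero_events_raise(self):
        with pytest.raises(ValueError):
            quadrant_fractions(stack_from(np.zeros((1, 2)), "DMC1"), "RAD51")

    def test_top_half_fraction(self):
        xy = np.array([[0.0, 10.0], [0.0, -10.0], [5.0, 3.0], [9.0, -1.0]])
        assert top_half_fraction(stack_from(xy), "RAD51") == 0.5


class TestFitSigma:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        xy = np.column_stack([rng.normal(scale=30, size=10000),
                              rng.normal(scale=50, size=10000)])
        sigma, fwhm = fit_sigma(stack_from(xy), "RAD51")
        assert sigma == pytest.approx(50.0, abs=2.0)
        assert fwhm / sigma == pytest.approx(2.355, abs=5e-4)

    def test_degenerate_coincident(self):
        xy = np.zeros((100, 2))
        with pytest.warns(UserWarning):
            sigma, fwhm = fit_sigma(stack_from(xy), "RAD51")
        assert sigma == 0.0 and fwhm == 0.0

    def test_too_few_events_raise(self, rng):
        with pytest.raises(ValueError):
            fit_sigma(stack_from(rng.normal(size=(10, 2))), "RAD51")


class TestStackDistances:
    def _d2r1(self, roi_id, dd, dr):
        """D2R1 with close at origin, far at (0, dd), RAD51 at (dr, 0)."""
        return analyze_configuration(roi_id, [
            make_nanofocus("DMC1", (0.0, 0.0)),
            make_nanofocus("DMC1", (0.0, dd)),
            make_nanofocus("RAD51", (dr, 0.0)),
        ])

    def test_hand_computed_mean_sem(self):
        configs = [self._d2r1("a", 300, 60), self._d2r1("b", 320, 70),
                   self._d2r1("c", 340, 80)]
        table = stack_distances({"zygotene": configs})
        dd = table[table["pair"] == "D-D"].iloc[0]
        assert dd["mean_nm"] == pytest.approx(320.0)
        assert dd["sem_nm"] == pytest.approx(20 / np.sqrt(3))
        closer = table[table["pair"] == "closeD-R"].iloc[0]
        assert closer["mean_nm"] == pytest.approx(70.0)
        assert closer["n"] == 3

    def test_single_config_sem_zero(self):
        table = stack_distances({"lep": [self._d2r1("a", 300, 60)]})
        assert (table["sem_nm"] == 0.0).all()

    def test_geometry_recovered_from_simulated_foci(self, rng):
        """Construction distances are recovered within Monte-Carlo error."""
        from nanofoci.d2r1_fit import analyze_d2r1_focus
        from nanofoci.simdata import D2R1Model, gen_d2r1_focus
        model = D2R1Model()
        configs = []
        for _ in range(25):
            focus = gen_d2r1_focus(model, rng)
            c = analyze_d2r1_focus(focus.points)
            if c.label == "D2R1":
                configs.append(c)
        table = stack_distances({"sim": configs})
        dd = table[table["pair"] == "D-D"].iloc[0]
        # 2D projection of a 400 nm offset: mean 400*pi/4 ~ 314 nm
        assert dd["mean_nm"] == pytest.approx(314.0, abs=30.0)

    def test_build_stack_aligns_goal_upward(self, rng):
        from nanofoci.nanoseg import segment_channels
        import pandas as pd
        from conftest import gaussian_cluster
        df = pd.concat([
            gaussian_cluster(rng, (0, 0), 15.0, 2000, "DMC1"),
            gaussian_cluster(rng, (80, 0), 15.0, 2000, "RAD51"),
        ], ignore_index=True)
        nf = segment_channels(df)
        config = analyze_configuration("r", nf["DMC1"] + nf["RAD51"])
        roi = make_roi("r", df)
        stack = build_stack([roi], [config], "DMC1", "RAD51")
        # RAD51 cloud centre now sits on the +y axis
        r_xy = stack.channel_xy("RAD51")
        assert np.mean(r_xy[:, 0]) == pytest.approx(0.0, abs=3.0)
        assert np.mean(r_xy[:, 1]) == pytest.approx(80.0, abs=5.0)
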