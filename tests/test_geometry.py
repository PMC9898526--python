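"""Fold-front measurement operators: resampling, triplet curvature, normal
speed, smoothing, ensemble filters, depth, tracking, thickness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldflow import (
    ConvergenceCenter,
    FoldFront,
    FrontSeries,
    ensemble_average,
    local_curvature,
    local_normal,
    neck_depth,
    normal_speed,
    resample_front,
    smooth_time,
    tissue_thickness,
    track_toward_center,
)
from foldflow.exceptions import ConfigurationError
from foldflow.geometry import _arclength_of_x, circumcircle_curvature


def line_front(z=0.0, time=0.0, x0=-200.0, x1=200.0, n=81):
    xs = np.linspace(x0, x1, n)
    return FoldFront(time=time, points=np.stack([xs, np.full(n, z)], axis=1))


def arc_front(r, theta0, theta1, n, center=(0.0, 0.0), time=0.0):
    th = np.linspace(theta0, theta1, n)
    pts = np.stack([center[0] + r * np.sin(th), center[1] - r * np.cos(th)], axis=1)
    return FoldFront(time=time, points=pts)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

class TestResample:
    def test_straight_segment_uniform_spacing(self):
        f = FoldFront(time=0, points=np.array([[0.0, 0.0], [4.0, 0.0], [10.0, 0.0]]))
        out = resample_front(f, 11)
        np.testing.assert_allclose(out.points[:, 0], np.arange(11.0), atol=1e-12)
        np.testing.assert_allclose(out.points[:, 1], 0.0, atol=1e-12)

    def test_quarter_circle_points_stay_near_circle(self, quarter_circle):
        # chord sagitta for 5 degree sampling of r=100 is ~0.095 um
        out = resample_front(quarter_circle, 201)
        r = np.linalg.norm(out.points - np.array([0.0, 100.0]), axis=1)
        assert np.max(np.abs(r - 100.0)) < 0.1

    def test_three_points_are_endpoints_plus_arclength_midpoint(self, quarter_circle):
        out = resample_front(quarter_circle, 3)
        np.testing.assert_allclose(out.points[0], quarter_circle.points[0])
        np.testing.assert_allclose(out.points[-1], quarter_circle.points[-1])
        s = out.arc_lengths()
        assert s[1] == pytest.approx(out.length / 2, rel=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(mult=st.integers(1, 5), seed=st.integers(0, 10_000))
    def test_arc_length_preserved_for_convex_fronts(self, mult, seed):
        # when the output nodes include every input vertex (uniform input,
        # node count a multiple) no corner is cut and length is preserved
        rng = np.random.default_rng(seed)
        r = rng.uniform(50.0, 300.0)
        span = rng.uniform(0.5, 2.5)
        theta = np.linspace(0.0, span, 13)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        f = FoldFront(time=0, points=pts)
        out = resample_front(f, 12 * mult + 1)
        assert out.length == pytest.approx(f.length, rel=1e-9)

    def test_dense_resampling_converges_to_input_length(self, quarter_circle):
        coarse = resample_front(quarter_circle, 5).length
        dense = resample_front(quarter_circle, 2001).length
        full = quarter_circle.length
        assert coarse <= full + 1e-12
        assert abs(dense - full) < abs(coarse - full)
        assert dense == pytest.approx(full, rel=1e-4)


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

class TestLocalCurvature:
    def test_circle_center_inward_gives_positive_inverse_radius(self):
        # 41 vertices over 90 um of arc: spacing 2.25 um, so the triplet
        # flanks at +-22.5 um land exactly on vertices of the circle
        f = arc_front(300.0, -0.15, 0.15, 41, center=(0.0, 300.0))
        s = f.arc_lengths()
        # half-span of exactly 10 chords so the flanks land on vertices
        assert local_curvature(f, s[20], half_span=s[30] - s[20]) == pytest.approx(
            1 / 300.0, rel=1e-12)

    def test_circle_center_outward_gives_negative_curvature(self):
        th = np.linspace(-0.15, 0.15, 41)
        pts = np.stack([300.0 * np.sin(th), -300.0 * (1 - np.cos(th))], axis=1)
        f = FoldFront(time=0, points=pts)
        s = f.arc_lengths()
        assert local_curvature(f, s[20], half_span=s[30] - s[20]) == pytest.approx(
            -1 / 300.0, rel=1e-12)

    def test_collinear_triplet_is_exactly_zero(self):
        assert local_curvature(line_front(), 200.0) == 0.0

    def test_out_of_support_anchor_signals_nan(self):
        f = line_front()
        assert np.isnan(local_curvature(f, 10.0))  # closer than 22.5 to the end
        assert np.isnan(local_curvature(f, f.length - 1.0))

    def test_ellipse_error_is_second_order_in_half_span(self):
        # analytic curvature of (a sin t, b(1-cos t)) is ab/(a^2cos^2+b^2sin^2)^1.5
        a, b = 300.0, 200.0
        t = np.linspace(-1.2, 1.2, 4001)
        f = FoldFront(time=0, points=np.stack([a * np.sin(t), b * (1 - np.cos(t))], axis=1))
        s0 = _arclength_of_x(f, 50.0)
        t0 = np.arcsin(50.0 / a)
        k_true = a * b / (a**2 * np.cos(t0) ** 2 + b**2 * np.sin(t0) ** 2) ** 1.5
        err_full = abs(local_curvature(f, s0, 22.5) - k_true)
        err_half = abs(local_curvature(f, s0, 11.25) - k_true)
        assert err_full < 2e-3 * k_true
        assert 2.5 < err_full / err_half < 5.5  # O(half_span^2) convergence

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(10.0, 10_000.0), seed=st.integers(0, 10_000))
    def test_exact_on_any_circle_triplet(self, r, seed):
        rng = np.random.default_rng(seed)
        th = np.sort(rng.uniform(0.0, 1.0, 3))
        while np.min(np.diff(th)) < 1e-3:
            th = np.sort(rng.uniform(0.0, 1.0, 3))
        p1, p2, p3 = (np.array([r * np.sin(t), r - r * np.cos(t)]) for t in th)
        assert circumcircle_curvature(p1, p2, p3) == pytest.approx(1 / r, rel=1e-9)


# ---------------------------------------------------------------------------
# normal speed
# ---------------------------------------------------------------------------

class TestNormalSpeed:
    def test_uniform_vertical_translation(self):
        f0 = line_front(z=0.0, time=0.0)
        f1 = line_front(z=5.0, time=0.25)
        for s in (50.0, 200.0, 350.0):
            assert normal_speed(f0, f1, s) == pytest.approx(20.0)

    def test_concentric_circles_speed_is_radius_change(self):
        f0 = arc_front(100.0, -1.0, 1.0, 201, center=(0, 100.0), time=0.0)
        f1 = arc_front(95.0, -1.0, 1.0, 201, center=(0, 100.0), time=1.0)
        assert normal_speed(f0, f1, f0.length / 2) == pytest.approx(5.0, rel=1e-6)

    def test_identical_fronts_zero_speed(self):
        f0 = line_front(time=0.0)
        f1 = line_front(time=1.0)
        assert normal_speed(f0, f1, 120.0) == pytest.approx(0.0, abs=1e-12)

    def test_normal_missing_next_front_signals_nan(self):
        f0 = line_front(time=0.0)
        f1 = FoldFront(time=1.0, points=np.array([[300.0, 5.0], [400.0, 5.0], [500.0, 5.0]]))
        assert np.isnan(normal_speed(f0, f1, 120.0))

    def test_normal_is_plus_z_oriented(self):
        n = local_normal(line_front(), 200.0)
        np.testing.assert_allclose(n, [0.0, 1.0], atol=1e-12)


# ---------------------------------------------------------------------------
# temporal smoothing
# ---------------------------------------------------------------------------

class TestSmoothTime:
    def test_constant_series_unchanged(self):
        t = np.arange(0, 5, 0.25)
        np.testing.assert_allclose(smooth_time(t, np.full(t.size, 3.3)), 3.3)

    def test_single_sample_unchanged(self):
        np.testing.assert_allclose(smooth_time([1.0], [7.0]), [7.0])

    def test_impulse_spread_over_seven_quarter_hour_frames(self):
        t = np.arange(0, 10, 0.25)
        v = np.zeros(t.size)
        v[20] = 8.0
        out = smooth_time(t, v, window=1.75)
        assert out[20] == pytest.approx(8.0 / 7.0)
        assert out[17] == pytest.approx(8.0 / 7.0)  # still inside +-0.875 h
        assert out[16] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# ensemble averaging with exclusion rules
# ---------------------------------------------------------------------------

def make_profile(n_animals, curvature=0.002, speed=1.0, jitter=0.0, time=20.0, pos=0.0):
    rows = []
    for i in range(n_animals):
        rows.append((f"a{i}", time, pos, curvature + jitter * (i - n_animals / 2), speed))
    return pd.DataFrame(rows, columns=["animal_id", "time", "position_ml", "curvature", "speed"])


class TestEnsembleAverage:
    def test_position_covered_by_four_animals_is_dropped(self):
        prof = pd.concat([make_profile(4, pos=0.0), make_profile(6, pos=30.0)])
        out = ensemble_average(prof)
        assert set(out["position_ml"]) == {30.0}
        assert out.attrs["removed_fraction"] == pytest.approx(0.5)

    def test_high_curvature_sem_excluded(self):
        # sem 0.003 > 0.002 threshold
        prof = make_profile(6, jitter=0.003 * np.sqrt(6) / 1.7)
        sem = prof.groupby("time")["curvature"].std(ddof=1).iloc[0] / np.sqrt(6)
        assert sem > 0.002
        assert ensemble_average(prof).empty

    def test_identical_animals_have_zero_sem_and_survive(self):
        prof = make_profile(10)
        out = ensemble_average(prof)
        assert len(out) == 1
        assert out["curvature_sem"].iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert out["n_animals"].iloc[0] == 10
        assert out.attrs["removed_fraction"] == 0.0


# ---------------------------------------------------------------------------
# depth, tracking, thickness
# ---------------------------------------------------------------------------

class TestDepthAndTracking:
    def test_translated_front_depth_equals_translation(self):
        series = FrontSeries("a", [line_front(z=0.0, time=16.0),
                                   line_front(z=12.0, time=20.0)])
        d = neck_depth(series, reference_time=16.0, ml_range=(-150, 150))
        assert d.loc[d.time == 20.0, "depth"].iloc[0] == pytest.approx(12.0)
        assert d.loc[d.time == 16.0, "depth"].iloc[0] == pytest.approx(0.0)

    def test_static_series_depth_zero(self):
        series = FrontSeries("a", [line_front(time=t) for t in (16.0, 18.0, 20.0)])
        d = neck_depth(series, reference_time=16.0)
        np.testing.assert_allclose(d["depth"], 0.0, atol=1e-12)

    def test_missing_reference_front_names_neck_depth(self):
        series = FrontSeries("a", [line_front(time=20.0)])
        with pytest.raises(ConfigurationError, match="neck_depth"):
            neck_depth(series, reference_time=16.0)

    def test_concentric_circle_trajectories_are_radial(self):
        center = ConvergenceCenter(x=0.0, z=100.0)
        fronts = [arc_front(r, -1.0, 1.0, 201, center=(0, 100.0), time=t)
                  for r, t in [(100.0, 0.0), (90.0, 1.0), (80.0, 2.0)]]
        traj = track_toward_center(FrontSeries("a", fronts), center,
                                   positions_ml=[30.0])
        sub = traj[~traj.truncated]
        # along a radius toward (0,100): direction constant
        v = sub[["x", "z"]].to_numpy() - np.array([0.0, 100.0])
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
        assert np.max(np.abs(dirs - dirs[0])) < 1e-9

    def test_stationary_front_trajectory_is_a_point(self):
        fronts = [line_front(time=t) for t in (0.0, 1.0, 2.0)]
        traj = track_toward_center(FrontSeries("a", fronts),
                                   ConvergenceCenter(0.0, 500.0), positions_ml=[40.0])
        assert traj["x"].nunique() == 1 and traj["z"].nunique() == 1

    def test_parallel_lines_thickness(self):
        apical = line_front(z=0.0, time=0.0)
        basal = line_front(z=10.0, time=0.0)
        th = tissue_thickness(apical, basal)
        np.testing.assert_allclose(th["thickness"].dropna(), 10.0, atol=1e-9)

    def test_coincident_fronts_zero_thickness(self):
        th = tissue_thickness(line_front(), line_front())
        np.testing.assert_allclose(th["thickness"].dropna(), 0.0, atol=1e-9)

    def test_concentric_circles_thickness(self):
        apical = arc_front(300.0, -0.5, 0.5, 201, center=(0, 300.0), time=0.0)
        basal = arc_front(290.0, -0.5, 0.5, 201, center=(0, 300.0), time=0.0)
        th = tissue_thickness(apical, basal)
        np.testing.assert_allclose(th["thickness"].dropna(), 10.0, atol=1e-3)
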