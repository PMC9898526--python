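"""Synthetic study generator: initial geometries, tension schedules,
forward-simulated ensembles, recoil traces, image fixtures, determinism."""

import numpy as np
import pytest

from foldflow import (
    FoldFront,
    SyntheticStudyConfig,
    local_curvature,
    make_flattened_contour,
    make_initial_front,
    make_tension_schedule,
    simulate_animal,
    simulate_ensemble,
    synth_fiber_image,
    synth_recoil_trace,
    synth_zstack,
)
from foldflow.exceptions import ConfigurationError
from foldflow.geometry import _arclength_of_x
from foldflow.simulate import default_tension_schedule, fold_angle


class TestInitialGeometry:
    def test_uniform_arc_points_equidistant_from_center(self):
        f = make_initial_front("uniform_arc", arc_radius=300.0, span=600.0, n_points=101)
        r = np.linalg.norm(f.points - np.array([0.0, 300.0]), axis=1)
        assert np.max(np.abs(r - 300.0)) < 1e-9

    def test_uniform_spacing_in_arc_length(self):
        f = make_initial_front("flattened_medial", n_points=61)
        seg = np.diff(f.arc_lengths())
        # vertex chords differ from continuum arc spacing by O((ds/r)^2)
        assert np.ptp(seg) / seg.mean() < 1e-3

    def test_flattened_medial_curvature_profile(self):
        f = make_initial_front("flattened_medial", arc_radius=300.0,
                               flat_half_width=100.0, span=600.0, n_points=241)
        # flat interior minus the 22.5 um triplet half-span: |x| <= 77.5
        for x in (-77.0, 0.0, 77.0):
            s = _arclength_of_x(f, x)
            assert local_curvature(f, s) == pytest.approx(0.0, abs=1e-12)
        for x in (-200.0, 200.0):  # fully on the circular flanks
            s = _arclength_of_x(f, x)
            # flank points interpolate on chords: exact up to sampling bias
            assert local_curvature(f, s) == pytest.approx(1 / 300.0, rel=1e-4)

    def test_flattened_lateral_one_straight_flank(self):
        f = make_initial_front("flattened_lateral", arc_radius=300.0,
                               flat_half_width=100.0, span=600.0, n_points=241)
        s = f.arc_lengths()
        straight = f.points[s <= 2.0 * 100.0 - 22.5 - 1e-9]
        # straightened portion: collinear within 1e-9
        d = np.diff(straight, axis=0)
        cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        np.testing.assert_allclose(cross, 0.0, atol=1e-9)
        # far flank still circular
        s_far = _arclength_of_x(f, 200.0)
        assert local_curvature(f, s_far) == pytest.approx(1 / 300.0, rel=1e-4)

    def test_near_infinite_radius_is_collinear(self):
        f = make_initial_front("uniform_arc", arc_radius=1e11, span=600.0, n_points=51)
        z_span = np.ptp(f.points[:, 1])
        assert z_span < 1e-6

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            make_initial_front("saddle")

    def test_degenerate_flat_width_rejected(self):
        with pytest.raises(ConfigurationError):
            make_initial_front("flattened_medial", flat_half_width=300.0, span=600.0)

    def test_flattened_contour_is_closed_with_flat_chord(self):
        f = make_flattened_contour(arc_radius=300.0, flat_half_width=100.0, n_points=400)
        assert f.closed
        clip_z = 300.0 - np.sqrt(300.0**2 - 100.0**2)
        assert f.points[:, 1].min() == pytest.approx(clip_z, abs=0.2)
        flat = f.points[np.abs(f.points[:, 1] - clip_z) < 1e-6]
        assert np.ptp(flat[:, 0]) > 150.0  # a real chord, not a point


class TestTensionSchedule:
    def test_constant(self):
        sched = make_tension_schedule("constant", [0.5])
        assert sched(19.3) == pytest.approx(0.5)

    def test_linear_ramp_midpoint(self):
        sched = make_tension_schedule("linear_ramp", [0.2, 0.6, 18.0, 24.0])
        assert sched(21.0) == pytest.approx(0.4)

    def test_linear_ramp_clamps_outside(self):
        sched = make_tension_schedule("linear_ramp", [0.2, 0.6, 18.0, 24.0])
        assert sched(30.0) == pytest.approx(0.6)
        assert sched(10.0) == pytest.approx(0.2)

    def test_piecewise_table(self):
        sched = make_tension_schedule("piecewise_table", [[18.0, 0.1], [20.0, 0.5]])
        assert sched(19.0) == pytest.approx(0.3)

    def test_negative_tension_rejected(self):
        with pytest.raises(ConfigurationError):
            make_tension_schedule("constant", [-0.1])

    def test_nonincreasing_breakpoints_rejected(self):
        with pytest.raises(ConfigurationError):
            make_tension_schedule("piecewise_table", [[20.0, 0.1], [18.0, 0.5]])


class TestSimulateAnimal:
    def test_zero_schedule_freezes_fronts(self):
        f0 = make_initial_front("uniform_arc", n_points=41)
        obs, _ = simulate_animal(f0, make_tension_schedule("constant", [0.0]),
                                 mu=1e-3, frame_interval=0.5, t_start=18.0, t_end=20.0)
        for f in obs.fronts:
            np.testing.assert_allclose(f.points, f0.points, atol=1e-12)

    def test_identical_seeds_bitwise_identical(self):
        f0 = make_initial_front("flattened_medial", n_points=41)
        sched = default_tension_schedule()
        kw = dict(mu=5e-4, frame_interval=0.5, t_start=18.0, t_end=19.0,
                  landmark_noise_sd=0.5, seed=7)
        a, _ = simulate_animal(f0, sched, **kw)
        b, _ = simulate_animal(f0, sched, **kw)
        for fa, fb in zip(a.fronts, b.fronts):
            assert np.array_equal(fa.points, fb.points)

    def test_noiseless_observation_equals_truth(self):
        f0 = make_initial_front("uniform_arc", n_points=41)
        obs, truth = simulate_animal(f0, default_tension_schedule(), mu=5e-4,
                                     frame_interval=0.5, t_start=18.0, t_end=19.0,
                                     landmark_noise_sd=0.0, landmark_spacing=None)
        for fo, ft in zip(obs.fronts, truth.fronts):
            np.testing.assert_allclose(fo.points, ft.points, atol=1e-12)


class TestSimulateEnsemble:
    def _config(self, **kw):
        base = dict(n_animals=3, t_start=18.0, t_end=19.0, frame_interval=0.5,
                    n_points=41, seed=5)
        base.update(kw)
        return SyntheticStudyConfig(**base)

    def test_no_noise_all_animals_identical(self):
        series, recoil, _ = simulate_ensemble(
            self._config(landmark_noise_sd=0.0, proxy_noise_cv=0.0))
        ref = series[0]
        for s in series[1:]:
            for fa, fb in zip(ref.fronts, s.fronts):
                np.testing.assert_allclose(fa.points, fb.points, atol=1e-12)

    def test_noiseless_recoil_equals_schedule(self):
        cfg = self._config(proxy_noise_cv=0.0, proxy_constant=1.0)
        _, recoil, truth = simulate_ensemble(cfg)
        expected = np.asarray(cfg.tension_schedule(recoil["dev_time"].to_numpy()))
        np.testing.assert_allclose(recoil["recoil"].to_numpy(), expected, rtol=1e-12)

    def test_animal_series_stable_under_ensemble_growth(self):
        small, _, _ = simulate_ensemble(self._config(n_animals=3))
        large, _, _ = simulate_ensemble(self._config(n_animals=5))
        for fa, fb in zip(small[2].fronts, large[2].fronts):
            assert np.array_equal(fa.points, fb.points)

    def test_landmark_noise_sd_calibrated(self):
        # >= 1e4 landmark coordinates; empirical sd within 5% of nominal
        cfg = SyntheticStudyConfig(n_animals=4, t_end=24.0, landmark_noise_sd=0.5,
                                   landmark_spacing=None, seed=11)
        series, _, truth = simulate_ensemble(cfg)
        disp = []
        for s in series:
            t = truth.true_fronts[s.animal_id]
            for fo, ft in zip(s.fronts, t.fronts):
                disp.append((fo.points - ft.points).ravel())
        disp = np.concatenate(disp)
        assert disp.size >= 10_000
        assert np.std(disp) == pytest.approx(0.5, rel=0.05)


class TestSynthRecoilTrace:
    def test_infinite_tau_limit_is_linear(self):
        tr = synth_recoil_trace(v0=1.0, tau=1e9, duration=30.0, dt=1.0)
        np.testing.assert_allclose(tr["displacement_um"], tr["t_s"], atol=1e-6)

    def test_closed_form_difference(self):
        tr = synth_recoil_trace(v0=0.5, tau=10.0, duration=10.0, dt=1.0)
        d = tr.set_index("t_s")["displacement_um"]
        expected = 0.5 * 10.0 * (np.exp(-0.1) - np.exp(-0.7))
        assert d.loc[7.0] - d.loc[1.0] == pytest.approx(expected, abs=1e-12)

    def test_seed_irrelevant_without_noise(self):
        a = synth_recoil_trace(1.0, 3.0, 10.0, 0.5, noise_sd=0.0, seed=1)
        b = synth_recoil_trace(1.0, 3.0, 10.0, 0.5, noise_sd=0.0, seed=2)
        assert a.equals(b)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_recoil_trace(1.0, 3.0, 10.0, 0.0)


class TestSynthFiberImage:
    def test_truth_records_folded_orientation(self):
        _, truth = synth_fiber_image([((10.0, 10.0), 30.0, 5.0, 0.4, 50.0)],
                                     (128, 128), 0.161)
        assert truth["orientation_deg"].iloc[0] == pytest.approx(30.0)
        assert truth["length_um"].iloc[0] == pytest.approx(5.0)

    def test_150_degrees_folds_to_30(self):
        _, truth = synth_fiber_image([((10.0, 10.0), 150.0, 5.0, 0.4, 50.0)],
                                     (128, 128), 0.161)
        assert truth["orientation_deg"].iloc[0] == pytest.approx(30.0)

    def test_zero_fibers_uniform_background(self):
        img, truth = synth_fiber_image([], (32, 32), 0.2, background=7.0)
        assert truth.empty
        np.testing.assert_allclose(img, 7.0)

    def test_fiber_outside_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_fiber_image([((1.0, 1.0), 0.0, 50.0, 0.4, 50.0)], (32, 32), 0.2)

    def test_fold_angle_convention(self):
        assert fold_angle(150.0) == pytest.approx(30.0)
        assert fold_angle(90.0) == pytest.approx(90.0)
        assert fold_angle(179.0) == pytest.approx(1.0)


class TestSynthZstack:
    def test_flat_surface_argmax_at_height(self):
        stack = synth_zstack(np.full((8, 8), 20.0), n_slices=40)
        np.testing.assert_array_equal(stack.argmax(axis=0), 20)

    def test_tilted_plane_argmax_tracks_plane(self):
        yy, xx = np.mgrid[0:16, 0:16]
        hm = 5.0 + 0.4 * xx  # avoids exact half-integer heights (argmax ties)
        stack = synth_zstack(hm, n_slices=20)
        np.testing.assert_array_equal(stack.argmax(axis=0), np.rint(hm).astype(int))

    def test_out_of_range_height_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_zstack(np.full((4, 4), 50.0), n_slices=40)

    def test_noisy_stack_still_valid_shape(self):
        stack = synth_zstack(np.full((4, 4), 5.0), n_slices=10,
                             signal_amplitude=1.0, noise_sd=50.0, seed=0)
        assert stack.shape == (10, 4, 4)
        assert np.isfinite(stack).all()
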