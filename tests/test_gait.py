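"""Step detection, the speed-adaptive moving average, and the step-length
regression loop."""

import numpy as np
import pytest

from voxmouse.gait import (
    BoutTrace,
    StepLengthModel,
    averaged_trajectory,
    bout_stats,
    detect_steps,
    fit_step_model,
    iterate_to_convergence,
    lateral_deviation,
    validity_correlations,
    window_frames,
)

FS = 100.0
TRUE_MODEL = StepLengthModel(slope=0.25, intercept=8.0)


class TestWindowFrames:
    def test_formula_with_odd_forcing(self):
        # d(160) = 48 mm -> 48/160*100 = 30 frames -> odd-forced to 31
        model = StepLengthModel(slope=0.25, intercept=8.0)
        assert window_frames(160.0, model, FS) == 31

    def test_slow_speed_clamps_to_61(self):
        assert window_frames(0.5, TRUE_MODEL, FS) == 61
        assert window_frames(0.0, TRUE_MODEL, FS) == 61

    def test_result_is_odd_and_clamped(self):
        for s in np.linspace(0.1, 500.0, 200):
            w = window_frames(float(s), TRUE_MODEL, FS)
            assert w % 2 == 1
            assert 5 <= w <= 61

    def test_window_monotone_in_speed(self):
        """With a positive intercept, slower never means a smaller window."""
        speeds = np.linspace(1.0, 400.0, 400)
        ws = [window_frames(float(s), TRUE_MODEL, FS) for s in speeds]
        assert all(a >= b for a, b in zip(ws, ws[1:]))


def sinusoid_bout(speed=150.0, cadence=None, amp=3.0, duration=2.0, arc_radius=None):
    """Planar bout with a sinusoidal lateral offset about a line (or arc)."""
    if cadence is None:
        cadence = speed / TRUE_MODEL.cycle_distance(speed)
    n = int(duration * FS)
    t = np.arange(n) / FS
    lat = amp * np.sin(2 * np.pi * cadence * t)
    if arc_radius is None:
        xy = np.column_stack([speed * t, lat])
    else:
        th = speed * t / arc_radius
        cx = (arc_radius + lat) * np.cos(th)
        cy = (arc_radius + lat) * np.sin(th)
        xy = np.column_stack([cx, cy])
    speeds = np.full(n, speed)
    return xy, speeds, cadence


class TestAveragedTrajectory:
    def test_straight_path_identity(self):
        xy = np.column_stack([np.arange(100.0), np.zeros(100)])
        avg = averaged_trajectory(xy, np.full(100, 100.0), TRUE_MODEL, FS)
        assert np.allclose(avg, xy, atol=1e-9)

    def test_one_cycle_window_cancels_oscillation(self):
        xy, speeds, cadence = sinusoid_bout()
        avg = averaged_trajectory(xy, speeds, TRUE_MODEL, FS)
        resid = np.abs(avg[31:-31, 1])
        assert resid.max() < 0.05 * 3.0

    def test_arc_bias_toward_inside(self):
        """On a circular arc the moving average sits inside the true path."""
        xy, speeds, _ = sinusoid_bout(amp=0.0, arc_radius=200.0)
        avg = averaged_trajectory(xy, speeds, TRUE_MODEL, FS)
        r_avg = np.hypot(avg[31:-31, 0], avg[31:-31, 1])
        assert np.all(r_avg < 200.0)

    def test_fixed_window_override(self):
        xy, speeds, _ = sinusoid_bout()
        a = averaged_trajectory(xy, speeds, fixed_window=31)
        b = averaged_trajectory(xy, speeds, TRUE_MODEL, FS)
        assert a.shape == b.shape


class TestLateralDeviation:
    def test_single_offset_frame(self):
        xy = np.column_stack([np.arange(50.0), np.zeros(50)])
        bumped = xy.copy()
        bumped[25, 1] = 3.0  # offset to the left of +x travel
        dev = lateral_deviation(bumped, xy)
        assert dev[25] == pytest.approx(3.0, abs=1e-6)
        assert np.max(np.abs(np.delete(dev, 25))) < 1e-9

    def test_sinusoid_amplitude_recovered(self):
        xy, speeds, cadence = sinusoid_bout()
        avg = averaged_trajectory(xy, speeds, TRUE_MODEL, FS)
        dev = lateral_deviation(xy, avg)
        assert abs(np.max(dev[31:-31]) - 3.0) < 0.15

    def test_sign_flips_with_travel_direction(self):
        xy = np.column_stack([np.arange(50.0), np.zeros(50)])
        bumped = xy.copy()
        bumped[:, 1] = 0.5
        dev_fwd = lateral_deviation(bumped, xy)
        dev_rev = lateral_deviation(bumped[::-1], xy[::-1])
        assert np.allclose(dev_fwd[5:-5], 0.5)
        assert np.allclose(dev_rev[5:-5], -0.5)

    def test_stationary_tangent_gives_zero(self):
        xy = np.ones((20, 2))
        assert np.allclose(lateral_deviation(xy + 0.1, xy), 0.0)


class TestDetectSteps:
    def test_sinusoid_two_events_per_cycle(self):
        t = np.arange(400) / FS
        dev = 3.0 * np.sin(2 * np.pi * 1.0 * t)  # 4 cycles
        steps = detect_steps(dev, FS)
        assert len(steps) == 8
        kinds = [s.kind for s in steps]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_flat_series_no_events(self):
        assert detect_steps(np.zeros(200), FS) == []

    def test_small_ripple_rejected(self):
        t = np.arange(400) / FS
        dev = 3.0 * np.sin(2 * np.pi * 1.0 * t) + 0.2 * np.sin(2 * np.pi * 30.0 * t)
        steps = detect_steps(dev, FS)
        assert len(steps) == 8


class TestBoutStats:
    def test_distance_per_step_division(self):
        xy, speeds, cadence = sinusoid_bout(speed=120.0, duration=2.0)
        bt = BoutTrace(xy, xy, speeds, FS)
        avg = averaged_trajectory(xy, speeds, TRUE_MODEL, FS)
        dev = lateral_deviation(xy, avg)
        steps = detect_steps(dev, FS)
        st = bout_stats(bt, steps, dev_front=dev, dev_rear=dev)
        assert st.is_gait_bout
        assert st.distance_per_step_mm * st.n_steps == pytest.approx(st.path_mm, rel=0.01)
        assert st.cadence_steps_s == pytest.approx(2 * cadence, rel=0.15)

    def test_too_few_steps_flagged(self):
        xy = np.column_stack([np.arange(20.0), np.zeros(20)])
        bt = BoutTrace(xy, xy, np.full(20, 100.0), FS)
        st = bout_stats(bt, [])
        assert not st.is_gait_bout


class TestFitStepModel:
    def _stats(self, speeds, noise=0.0, rng=None):
        from voxmouse.gait import GaitBoutStats

        out = []
        for s in speeds:
            d_cycle = TRUE_MODEL.cycle_distance(s)
            if noise and rng is not None:
                d_cycle = d_cycle + rng.normal(0, noise)
            out.append(
                GaitBoutStats(
                    avg_speed_mm_s=float(s),
                    n_steps=10,
                    distance_per_step_mm=d_cycle / 2.0,
                    cadence_steps_s=5.0,
                    mean_abs_dev_front_mm=1.0,
                    mean_abs_dev_rear_mm=2.0,
                    path_mm=5.0 * d_cycle,
                    duration_s=2.0,
                )
            )
        return out

    def test_exact_recovery_on_noise_free_points(self):
        stats = self._stats([80.0, 150.0, 220.0, 300.0])
        m = fit_step_model(stats)
        assert m.slope == pytest.approx(0.25, abs=1e-9)
        assert m.intercept == pytest.approx(8.0, abs=1e-7)
        assert m.r2 == pytest.approx(1.0)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        speeds = rng.uniform(60, 250, 50)
        stats = self._stats(speeds, noise=2.0, rng=rng)
        m = fit_step_model(stats)
        sx = np.std(speeds, ddof=1)
        se = 2.0 / (sx * np.sqrt(50))
        assert abs(m.slope - 0.25) < 3 * se

    def test_degenerate_designs_fall_back(self):
        with pytest.warns(UserWarning):
            m = fit_step_model(self._stats([100.0, 100.0, 100.0]))
        assert (m.slope, m.intercept) == (0.3, 10.0)
        with pytest.warns(UserWarning):
            m = fit_step_model(self._stats([100.0]))
        assert (m.slope, m.intercept) == (0.3, 10.0)


class TestIterateToConvergence:
    def _bouts(self, speeds=(110.0, 150.0, 190.0, 230.0), amp=3.0):
        bouts = []
        for s in speeds:
            xy, sp, _ = sinusoid_bout(speed=s, amp=amp, duration=2.0)
            bouts.append(BoutTrace(xy, xy, sp, FS))
        return bouts

    def test_converges_quickly_on_self_consistent_data(self):
        model, stats = iterate_to_convergence(self._bouts())
        assert model.iterations <= 3
        assert len(stats) == 4

    def test_recovers_generating_model(self):
        model, _ = iterate_to_convergence(self._bouts())
        assert abs(model.slope - 0.25) < 0.1 * 0.25 + 0.02
        pred = model.cycle_distance(170.0)
        assert pred == pytest.approx(TRUE_MODEL.cycle_distance(170.0), rel=0.1)

    def test_deterministic(self):
        m1, _ = iterate_to_convergence(self._bouts())
        m2, _ = iterate_to_convergence(self._bouts())
        assert m1.slope == m2.slope and m1.intercept == m2.intercept

    def test_averaged_path_is_self_consistent(self):
        """The averaged trajectory's own lateral deviation is ~0."""
        xy, speeds, _ = sinusoid_bout()
        avg = averaged_trajectory(xy, speeds, TRUE_MODEL, FS)
        avg2 = averaged_trajectory(avg, speeds, TRUE_MODEL, FS)
        dev = lateral_deviation(avg, avg2)
        rms = np.sqrt(np.mean(dev[31:-31] ** 2))
        assert rms < 0.02 * 3.0


class TestValidityCorrelations:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        out = validity_correlations({"m": x}, {"s": 2 * x + 1, "neg": -x})
        assert out["m_vs_s"]["r"] == pytest.approx(1.0)
        assert out["m_vs_neg"]["r"] == pytest.approx(-1.0)

    def test_bivariate_normal_within_fisher_interval(self):
        rng = np.random.default_rng(7)
        rho, n = 0.7, 14
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, n)
        out = validity_correlations({"m": xy[:, 0]}, {"s": xy[:, 1]})
        z = np.arctanh(rho)
        half = 1.96 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
        assert lo <= out["m_vs_s"]["r"] <= hi

    def test_zero_variance_flagged(self):
        out = validity_correlations({"m": [1.0, 1.0, 1.0]}, {"s": [1.0, 2.0, 3.0]})
        assert out["m_vs_s"]["zero_variance"]
        assert np.isnan(out["m_vs_s"]["r"])

    def test_too_few_animals(self):
        with pytest.raises(ValueError):
            validity_correlations({"m": [1.0, 2.0]}, {"s": [1.0, 2.0]})
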