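"""Microsaccade detection: thresholds, elliptic criterion, characterization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import msreach as mr
from msreach.errors import DegenerateThresholdError
from msreach.synth import minimum_jerk_step

from .oracles import brute_force_detect, median_sd, smooth_random_trace


def vel_series(v, rate=1000.0):
    v = np.asarray(v, float)
    return mr.SampledSeries(np.arange(len(v)) / rate, v, rate)


class TestThresholds:
    def test_hand_computed_example(self):
        # vx = [-2,-2,0,2,2]: median 0, median of squares 4 => sigma 2, eta 10
        v = np.column_stack([[-2.0, -2, 0, 2, 2], [-1.0, 0, 1, 2, -2]])
        thr = mr.compute_thresholds(vel_series(v), lam=5.0)
        assert thr.sigma_x == pytest.approx(2.0)
        assert thr.eta_x == pytest.approx(10.0)

    def test_homogeneity_under_scaling(self, rng):
        v = rng.normal(size=(200, 2))
        t1 = mr.compute_thresholds(vel_series(v))
        t3 = mr.compute_thresholds(vel_series(3.0 * v))
        assert t3.eta_x == pytest.approx(3.0 * t1.eta_x, rel=1e-12)
        assert t3.eta_y == pytest.approx(3.0 * t1.eta_y, rel=1e-12)

    def test_matches_independent_median_sd(self, rng):
        v = rng.normal(1.0, 2.0, size=(501, 2))
        thr = mr.compute_thresholds(vel_series(v), lam=5.0)
        assert thr.sigma_x == pytest.approx(median_sd(v[:, 0]), rel=1e-12)
        assert thr.sigma_y == pytest.approx(median_sd(v[:, 1]), rel=1e-12)

    def test_degenerate_axis_named(self):
        v = np.column_stack([np.ones(50), np.random.default_rng(0).normal(size=50)])
        with pytest.raises(DegenerateThresholdError, match="x"):
            mr.compute_thresholds(vel_series(v))


def make_thresholds(eta_x=5.0, eta_y=5.0):
    return mr.VelocityThresholds(eta_x=eta_x, eta_y=eta_y, lam=5.0,
                                 sigma_x=eta_x / 5, sigma_y=eta_y / 5)


class TestDetection:
    def test_zero_velocity_no_events(self):
        v = vel_series(np.zeros((2000, 2)))
        assert mr.detect_microsaccades(v, make_thresholds()) == []

    def test_boundary_sample_not_outside(self):
        # a sample exactly on the ellipse is not an event (strict inequality)
        v = np.zeros((2000, 2))
        v[100:200, 0] = 5.0  # exactly eta_x
        assert mr.detect_microsaccades(vel_series(v), make_thresholds()) == []
        v[100:200, 0] = 5.0001
        assert len(mr.detect_microsaccades(vel_series(v), make_thresholds())) == 1

    def test_short_runs_discarded(self):
        v = np.zeros((2000, 2))
        v[100:139, 0] = 50.0  # 39 samples < 40
        assert mr.detect_microsaccades(vel_series(v), make_thresholds()) == []
        v[100:140, 0] = 50.0  # 40 samples
        events = mr.detect_microsaccades(vel_series(v), make_thresholds())
        assert len(events) == 1
        assert events[0].t_onset == pytest.approx(0.100)
        assert events[0].t_offset == pytest.approx(0.139)

    def test_injected_step_recovered_on_low_noise(self):
        # 60-ms, 0.9-cm displacement in a quiet trace: exactly one event,
        # onset within 5 ms of the injected onset (detector property, so no
        # low-pass filtering, whose non-causal smoothing spreads the step)
        rng = np.random.default_rng(3)
        n = 3000
        t = np.arange(n) * 0.001
        pos = rng.normal(0.0, 0.001, (n, 2))
        onset, dur, amp = 1.0, 0.060, 0.9
        pos[:, 0] += amp * minimum_jerk_step(t - onset, dur)
        series = mr.SampledSeries(t, pos, 1000.0)
        vel = mr.moving_window_velocity(series)
        thr = mr.compute_thresholds(vel)
        events = mr.detect_microsaccades(vel, thr, pos=series)
        assert len(events) == 1
        assert events[0].t_onset == pytest.approx(onset, abs=0.005)
        assert events[0].amplitude == pytest.approx(amp, rel=0.1)

    def test_equivalence_with_bruteforce_scan(self, rng):
        for _ in range(10):
            n = int(rng.integers(500, 5000))
            t, v = smooth_random_trace(rng, n, n_events=int(rng.integers(0, 5)))
            series = vel_series(v)
            thr = mr.compute_thresholds(series)
            got = mr.detect_microsaccades(series, thr)
            got_idx = [
                (int(round(e.t_onset * 1000)), int(round(e.t_offset * 1000)))
                for e in got
            ]
            expected = brute_force_detect(v[:, 0], v[:, 1], t, thr.eta_x, thr.eta_y)
            assert got_idx == expected

    def test_scale_invariance(self, rng):
        t, v = smooth_random_trace(rng, 3000, n_events=3)
        base = None
        for c in (0.1, 1.0, 7.5):
            series = vel_series(c * v)
            thr = mr.compute_thresholds(series)
            idx = [
                (round(e.t_onset, 6), round(e.t_offset, 6))
                for e in mr.detect_microsaccades(series, thr)
            ]
            base = idx if base is None else base
            assert idx == base

    def test_lambda_monotonicity(self, rng):
        t, v = smooth_random_trace(rng, 4000, n_events=4)
        series = vel_series(v)
        counts = []
        for lam in (2, 3, 5, 8, 12):
            thr = mr.compute_thresholds(series, lam=lam)
            counts.append(len(mr.detect_microsaccades(series, thr)))
        assert counts == sorted(counts, reverse=True)

    def test_window_restriction(self):
        v = np.zeros((3000, 2))
        v[100:200, 0] = 50.0
        v[2500:2600, 0] = 50.0
        events = mr.detect_microsaccades(
            vel_series(v), make_thresholds(), t_start=1.0, t_end=3.0
        )
        assert len(events) == 1
        assert events[0].t_onset >= 1.0


class TestCharacterize:
    def test_pure_horizontal_step(self):
        n = 500
        t = np.arange(n) * 0.001
        pos = np.zeros((n, 2))
        pos[250:, 0] = 0.5
        vel = mr.differentiate(mr.SampledSeries(t, pos, 1000.0))
        amp, dur, peak = mr.characterize_event(
            mr.SampledSeries(t, pos, 1000.0), vel, 0.2, 0.3
        )
        assert amp == pytest.approx(0.5)
        assert dur == pytest.approx(0.1)
        assert peak > 0

    def test_three_four_five_triangle(self):
        n = 500
        t = np.arange(n) * 0.001
        pos = np.zeros((n, 2))
        pos[300:, 0] = 0.3
        pos[300:, 1] = 0.4
        vel = mr.differentiate(mr.SampledSeries(t, pos, 1000.0))
        amp, _, _ = mr.characterize_event(
            mr.SampledSeries(t, pos, 1000.0), vel, 0.25, 0.35
        )
        assert amp == pytest.approx(0.5)

    def test_peak_speed_recovery_noiseless(self):
        n = 2000
        t = np.arange(n) * 0.001
        pos = np.zeros((n, 2))
        onset, dur, amp = 0.8, 0.08, 1.2
        pos[:, 1] = amp * minimum_jerk_step(t - onset, dur)
        s = mr.SampledSeries(t, pos, 1000.0)
        vel = mr.moving_window_velocity(s)
        _, _, peak = mr.characterize_event(s, vel, onset, onset + dur)
        assert peak == pytest.approx(1.875 * amp / dur, rel=0.02)
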