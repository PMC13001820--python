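"""Synthetic-data generator: kinematic closed forms, event statistics,
determinism."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import msreach as mr
from msreach.errors import DomainError
from msreach.synth import sample_events, stationary_hand


def make_schedule(condition=mr.Condition.CUE_MONITORING, t_go=1.9, t_end=3.0,
                  cursor_d=None):
    return mr.EventSchedule(
        condition=condition, t_show_target=0.0, t_go=t_go, t_trial_end=t_end,
        cursor_move_duration=cursor_d,
    )


class TestMinimumJerk:
    @pytest.mark.parametrize(
        "t, d, a, expected",
        [(0.0, 1.25, 20.0, 0.0), (1.25, 1.25, 20.0, 20.0), (0.625, 1.25, 20.0, 10.0)],
    )
    def test_boundary_and_midpoint(self, t, d, a, expected):
        assert mr.minimum_jerk_position(t, d, a) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            mr.minimum_jerk_position(-0.1, 1.0, 20.0)
        with pytest.raises(DomainError):
            mr.minimum_jerk_position(1.1, 1.0, 20.0)
        with pytest.raises(DomainError):
            mr.minimum_jerk_position(0.5, 0.0, 20.0)

    def test_endpoint_derivatives_vanish(self):
        # velocity and acceleration are zero at both endpoints (closed form)
        d, a = 1.36, 20.0
        eps = 1e-6
        t = np.array([0.0, eps, d - eps, d])
        y = mr.minimum_jerk_position(t, d, a)
        assert abs(y[1] - y[0]) / eps < 1e-4          # v(0) ~ 0
        assert abs(y[3] - y[2]) / eps < 1e-4          # v(d) ~ 0
        assert mr.minimum_jerk_velocity(0.0, d, a) == 0.0
        assert mr.minimum_jerk_velocity(d, d, a) == 0.0

    def test_peak_speed_closed_form_vs_numeric(self):
        d, a = 1.36, 20.0
        t = np.linspace(0, d, 20001)
        v_num = np.gradient(mr.minimum_jerk_position(t, d, a), t)
        peak = 1.875 * a / d
        assert v_num.max() == pytest.approx(peak, rel=1e-6)
        assert t[np.argmax(v_num)] == pytest.approx(d / 2, abs=1e-3)

    @given(st.floats(0.0, 1.0))
    def test_monotone_nondecreasing(self, frac):
        d, a = 1.2, 20.0
        t = frac * d
        y1 = mr.minimum_jerk_position(t, d, a)
        y2 = mr.minimum_jerk_position(min(t + 0.01, d), d, a)
        assert y2 >= y1 - 1e-12


class TestCursorTrajectory:
    def test_bow_maximum_at_midpoint(self):
        traj = mr.generate_cursor_trajectory(a=20, d=1.25, bow_direction="right",
                                             dt=0.001)
        i = int(np.argmax(np.abs(traj.xy[:, 0])))
        assert np.abs(traj.xy[:, 0]).max() == pytest.approx(0.25, abs=1e-12)
        assert traj.t[i] == pytest.approx(0.625, abs=1e-3)
        assert traj.xy[0, 0] == 0.0
        assert traj.xy[-1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_final_position_is_target_offset(self):
        traj = mr.generate_cursor_trajectory(a=20, d=1.25)
        assert traj.xy[-1, 1] == pytest.approx(20.0, abs=1e-9)

    def test_left_mirrors_right(self):
        r = mr.generate_cursor_trajectory(bow_direction="right")
        l = mr.generate_cursor_trajectory(bow_direction="left")
        np.testing.assert_allclose(l.xy[:, 0], -r.xy[:, 0])
        np.testing.assert_allclose(l.xy[:, 1], r.xy[:, 1])

    def test_single_extremum(self):
        traj = mr.generate_cursor_trajectory()
        dx = np.diff(traj.xy[:, 0])
        # sign changes exactly once: rising to midpoint then falling
        assert int(np.sum(np.diff(np.sign(dx[dx != 0])) != 0)) == 1


class TestEventSampling:
    def test_zero_rate_gives_no_events(self, rng):
        assert sample_events(mr.ConstantRate(0.0), -2.0, 1.0, rng) == []

    def test_poisson_count_statistics(self):
        # 200 windows of 3 s at 1 Hz: total count within 3 SD of 600
        rng = np.random.default_rng(7)
        total = sum(
            len(sample_events(mr.ConstantRate(1.0), 0.0, 3.0, rng))
            for _ in range(200)
        )
        assert abs(total - 600) <= 3 * np.sqrt(600)

    def test_events_non_overlapping_and_inside_window(self, rng):
        evs = sample_events(mr.ConstantRate(3.0), -2.0, 1.0, rng)
        prev_end = -np.inf
        for onset, dur, amp in evs:
            assert onset >= prev_end
            assert -2.0 <= onset and onset + dur <= 1.0
            prev_end = onset + dur

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            mr.ConstantRate(-1.0)
        with pytest.raises(DomainError):
            mr.InhibitionProfile(dip=-0.1)


class TestGazeSimulation:
    def test_zero_rate_no_injected_events(self):
        sched = make_schedule()
        series, events = mr.simulate_fixational_gaze(
            sched, mr.ConstantRate(0.0), seed=0
        )
        assert events == []
        assert series.rate_hz == 500

    def test_gaze_stays_near_target(self):
        sched = make_schedule()
        series, _ = mr.simulate_fixational_gaze(
            sched, mr.InhibitionProfile(), seed=11
        )
        dist = np.hypot(series.xy[:, 0], series.xy[:, 1] - 20.0)
        assert dist.max() < 6.0

    def test_main_sequence_peak_velocity_scales_with_amplitude(self):
        sched = make_schedule()
        _, events = mr.simulate_fixational_gaze(
            sched, mr.ConstantRate(2.0), seed=5
        )
        assert len(events) >= 2
        for e in events:
            assert e.peak_velocity == pytest.approx(1.875 * e.amplitude / e.duration)

    def test_determinism(self):
        sched = make_schedule()
        s1, e1 = mr.simulate_fixational_gaze(sched, mr.InhibitionProfile(), seed=3)
        s2, e2 = mr.simulate_fixational_gaze(sched, mr.InhibitionProfile(), seed=3)
        np.testing.assert_array_equal(s1.xy, s2.xy)
        assert [e.t_onset for e in e1] == [e.t_onset for e in e2]


class TestHandSimulation:
    def test_noiseless_reach_reaches_amplitude(self):
        sched = make_schedule(mr.Condition.REACH_VISIBLE, t_go=1.9, t_end=4.0)
        hand, t_on, t_off = mr.simulate_hand_reach(
            sched, rt=0.4, d=1.36, a=20.0, noise_sd=0.0, seed=0
        )
        i_off = int(round(t_off * 1000))
        assert hand.xy[i_off, 1] == pytest.approx(20.0, abs=1e-9)
        assert t_on == pytest.approx(1.9 + 0.4)

    def test_noiseless_peak_speed(self):
        sched = make_schedule(mr.Condition.REACH_VISIBLE, t_go=1.9, t_end=4.0)
        hand, _, _ = mr.simulate_hand_reach(
            sched, rt=0.4, d=1.36, a=20.0, noise_sd=0.0, seed=0
        )
        speed = np.hypot(*np.gradient(hand.xy, hand.dt, axis=0).T)
        assert speed.max() == pytest.approx(1.875 * 20.0 / 1.36, rel=1e-4)

    def test_stationary_before_onset(self):
        sched = make_schedule(mr.Condition.REACH_VISIBLE, t_go=1.9, t_end=4.0)
        hand, t_on, _ = mr.simulate_hand_reach(
            sched, rt=0.4, d=1.36, a=20.0, noise_sd=0.0, seed=0
        )
        before = hand.t < t_on
        np.testing.assert_allclose(hand.xy[before], 0.0, atol=1e-12)


class TestDatasetGeneration:
    def test_counts_and_conditions(self):
        trials = mr.generate_dataset(
            n_participants=2, n_trials_per_condition=3, seed=1
        )
        assert len(trials) == 2 * 4 * 3
        conds = {t.schedule.condition for t in trials}
        assert conds == set(mr.Condition)

    def test_determinism(self):
        a = mr.generate_dataset(n_participants=1, n_trials_per_condition=2, seed=9)
        b = mr.generate_dataset(n_participants=1, n_trials_per_condition=2, seed=9)
        for ta, tb in zip(a, b):
            assert ta.trial_id == tb.trial_id
            np.testing.assert_array_equal(ta.gaze.xy, tb.gaze.xy)
            np.testing.assert_array_equal(ta.hand.xy, tb.hand.xy)

    def test_rt_exclusion_fixture_flagged(self):
        trial = mr.generate_trial(
            "P01", 0, mr.Condition.REACH_VISIBLE, seed=2,
            violation="rt_below_100ms",
        )
        assert trial.ground_truth.violations == ["rt_below_100ms_or_missing_eye"]
        assert trial.ground_truth.reaction_time < 0.1

    def test_violation_free_dataset_has_no_flags(self):
        trials = mr.generate_dataset(
            n_participants=1, n_trials_per_condition=2, seed=4
        )
        assert all(not t.ground_truth.violations for t in trials)

    def test_condition_specific_endings(self):
        cfg = mr.SimulatorConfig()
        mon = mr.generate_trial("P", 0, mr.Condition.CUE_MONITORING, cfg, seed=1)
        assert mon.schedule.t_trial_end == pytest.approx(
            mon.schedule.t_go + 0.3 + 0.8
        )
        trk = mr.generate_trial("P", 0, mr.Condition.CURSOR_TRACKING, cfg, seed=1)
        assert trk.schedule.t_trial_end == pytest.approx(
            trk.schedule.t_go + 0.3 + trk.schedule.cursor_move_duration
        )
        inv = mr.generate_trial("P", 0, mr.Condition.REACH_INVISIBLE, cfg, seed=1)
        assert inv.cursor is None
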