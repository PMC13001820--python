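"""Synthetic four-condition eye–hand datasets with known ground truth.

The generator emulates the recorded signals of the reaching task: fixational
gaze at 500 Hz around a target 20 cm above the hand start position, with
drift, measurement noise, and injected microsaccades whose rate is
time-varying (high during early fixation, ramping down toward the go cue,
dipping just after it, partially rebounding later); hand/cursor movement at
1000 Hz following a minimum-jerk trajectory; and the four trial conditions
(cue monitoring, cursor tracking, reach visible, reach invisible) with their
condition-specific endings.

Default parameters are the task's values: 1.8–2.0-s delay, 0.3-s post-cue
delay, 0.8-s cue-monitoring window, 1.15–1.35-s cursor movement with a
0.25-cm lateral bow, 20-cm reach amplitude.  Behavioural defaults follow the
group means observed in this task: microsaccades of ~0.95-cm amplitude and
~86-ms duration, baseline rate 1.26 Hz falling to 0.20 Hz before the cue with
a 0.11-Hz post-cue dip and 0.60-Hz rebound, reaction-time medians 0.38 s
(cursor visible) / 0.45 s (invisible), reach duration ~1.36 s.

Every generator is a pure function of its parameters and seed.  Trials can be
flagged to violate one of the exclusion rules, and the planted violation is
recorded in the ground truth so the exclusion stage can be tested exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError
from .preprocess import SampledSeries
from .types import (
    Condition,
    EventSchedule,
    GeometryConfig,
    GroundTruth,
    MicrosaccadeEvent,
    TrialRecord,
    RULE_RT_OR_MISSING_EYE,
    RULE_FIXATION_START_LATE,
    RULE_FIXATION_END_EARLY,
    RULE_LANDING_GT_6CM,
)

__all__ = [
    "minimum_jerk_position",
    "minimum_jerk_velocity",
    "minimum_jerk_step",
    "generate_cursor_trajectory",
    "ConstantRate",
    "LinearRamp",
    "InhibitionProfile",
    "sample_events",
    "simulate_fixational_gaze",
    "simulate_hand_reach",
    "SimulatorConfig",
    "generate_trial",
    "generate_dataset",
]

#: violation labels accepted by the generator, mapped to the exclusion-rule
#: code they are expected to trip
VIOLATION_RULES = {
    "rt_below_100ms": RULE_RT_OR_MISSING_EYE,
    "missing_eye": RULE_RT_OR_MISSING_EYE,
    "fixation_start_late": RULE_FIXATION_START_LATE,
    "fixation_end_early": RULE_FIXATION_END_EARLY,
    "landing_gt_6cm": RULE_LANDING_GT_6CM,
}


# ---------------------------------------------------------------------------
# minimum-jerk kinematics
# ---------------------------------------------------------------------------

def minimum_jerk_position(t, d: float, a: float):
    """Minimum-jerk displacement a·(10τ³ − 15τ⁴ + 6τ⁵), τ = t/d.

    Parameters are time ``t`` (s, scalar or array, within [0, d]), movement
    duration ``d`` (s) and amplitude ``a`` (cm).  Velocity and acceleration
    vanish at both endpoints.
    """
    if d <= 0:
        raise DomainError("movement duration must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > d + 1e-12):
        raise DomainError("t outside [0, d]")
    tau = np.clip(t_arr / d, 0.0, 1.0)
    out = a * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return float(out) if np.isscalar(t) else out


def minimum_jerk_velocity(t, d: float, a: float):
    """Closed-form minimum-jerk speed (a/d)·30τ²(1−τ)²; peak 1.875·a/d at τ=½."""
    if d <= 0:
        raise DomainError("movement duration must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > d + 1e-12):
        raise DomainError("t outside [0, d]")
    tau = np.clip(t_arr / d, 0.0, 1.0)
    out = (a / d) * 30 * tau**2 * (1 - tau) ** 2
    return float(out) if np.isscalar(t) else out


def minimum_jerk_step(t, d: float):
    """Normalized 0→1 smooth step (clamped outside [0, d])."""
    tau = np.clip(np.asarray(t, dtype=float) / d, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_cursor_trajectory(
    a: float = 20.0,
    d: float = 1.25,
    bow_direction: str = "right",
    dt: float = 0.001,
    bow_amplitude: float = 0.25,
) -> SampledSeries:
    """Curved cursor movement from start to target.

    Vertical position follows the minimum-jerk profile; the horizontal
    position bows out by at most ``bow_amplitude`` cm (default 0.25) at the
    movement midpoint, as a half-sine returning to midline at the target.
    """
    if a <= 0 or d <= 0 or dt <= 0:
        raise DomainError("a, d and dt must be positive")
    if bow_direction not in ("left", "right"):
        raise DomainError("bow_direction must be 'left' or 'right'")
    n = int(round(d / dt)) + 1
    t = np.arange(n) * dt
    y = minimum_jerk_position(np.minimum(t, d), d, a)
    sign = 1.0 if bow_direction == "right" else -1.0
    x = sign * bow_amplitude * np.sin(np.pi * np.minimum(t, d) / d)
    return SampledSeries(t, np.column_stack([x, y]), 1.0 / dt)


# ---------------------------------------------------------------------------
# time-varying microsaccade rate profiles
# ---------------------------------------------------------------------------

@dataclass
class ConstantRate:
    """Homogeneous event rate (Hz)."""

    rate: float

    def __post_init__(self):
        if self.rate < 0:
            raise DomainError("rate must be non-negative")

    def rate_at(self, t_rel_go):
        return np.full_like(np.asarray(t_rel_go, dtype=float), self.rate)

    def descriptor(self) -> dict:
        return {"name": "constant", **asdict(self)}


@dataclass
class LinearRamp:
    """Rate r0 before t0, linear to r1 at t1, r1 after (times relative to go)."""

    r0: float
    r1: float
    t0: float
    t1: float

    def __post_init__(self):
        if self.r0 < 0 or self.r1 < 0:
            raise DomainError("rates must be non-negative")
        if not self.t0 < self.t1:
            raise DomainError("t0 must precede t1")

    def rate_at(self, t_rel_go):
        return np.interp(
            np.asarray(t_rel_go, dtype=float), [self.t0, self.t1], [self.r0, self.r1]
        )

    def descriptor(self) -> dict:
        return {"name": "linear_ramp", **asdict(self)}


@dataclass
class InhibitionProfile:
    """Piecewise rate mirroring the task's oculomotor-inhibition time course.

    Baseline during early fixation, linear ramp down over the last second
    before the go cue, a brief post-cue dip, then a partial rebound.  Default
    levels are the group means observed in the task (Hz).
    """

    baseline: float = 1.26
    pre_cue: float = 0.20
    dip: float = 0.11
    rebound: float = 0.60
    ramp_start: float = -1.0
    dip_start: float = 0.10
    dip_end: float = 0.25
    rebound_at: float = 0.30

    def __post_init__(self):
        for name in ("baseline", "pre_cue", "dip", "rebound"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    def rate_at(self, t_rel_go):
        xp = [self.ramp_start, 0.0, self.dip_start, self.dip_end, self.rebound_at]
        fp = [self.baseline, self.pre_cue, self.dip, self.dip, self.rebound]
        return np.interp(np.asarray(t_rel_go, dtype=float), xp, fp)

    def descriptor(self) -> dict:
        return {"name": "inhibition", **asdict(self)}


RateProfile = Union[ConstantRate, LinearRamp, InhibitionProfile]


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------

def sample_events(
    profile: RateProfile,
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
    duration_mean: float = 0.086,
    duration_sd: float = 0.015,
    duration_range: tuple[float, float] = (0.05, 0.14),
    amplitude_mean: float = 0.95,
    amplitude_sd: float = 0.25,
    amplitude_range: tuple[float, float] = (0.3, 2.0),
    min_gap: float = 0.020,
) -> list[tuple[float, float, float]]:
    """Draw (onset, duration, amplitude) triples from an inhomogeneous
    Poisson process with the given rate profile (times relative to go cue).

    Onsets are sampled by thinning against the profile maximum.  Events are
    made non-overlapping by shifting a colliding onset just past the previous
    offset (preserving the Poisson count statistics); an event shifted past
    ``t_end`` is dropped.
    """
    if t_end <= t_start:
        raise DomainError("t_end must exceed t_start")
    grid = np.linspace(t_start, t_end, 512)
    rates = np.asarray(profile.rate_at(grid), dtype=float)
    if np.any(rates < 0):
        raise DomainError("rate profile is negative inside the window")
    rmax = float(rates.max())
    if rmax == 0.0:
        return []
    n_cand = rng.poisson(rmax * (t_end - t_start))
    cand = np.sort(rng.uniform(t_start, t_end, n_cand))
    accept = rng.uniform(0.0, 1.0, n_cand) * rmax < profile.rate_at(cand)
    onsets = cand[accept]
    k = onsets.size
    durations = np.clip(
        rng.normal(duration_mean, duration_sd, k), *duration_range
    )
    amplitudes = np.clip(
        rng.normal(amplitude_mean, amplitude_sd, k), *amplitude_range
    )
    events = []
    prev_end = -np.inf
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        if onset < prev_end + min_gap:
            onset = prev_end + min_gap
        if onset + dur > t_end:
            continue
        events.append((float(onset), float(dur), float(amp)))
        prev_end = onset + dur
    return events


# ---------------------------------------------------------------------------
# gaze simulation (500 Hz)
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _add_step(xy: np.ndarray, t: np.ndarray, t_on: float, dur: float, vec: np.ndarray):
    """Add a smooth displacement step ``vec`` starting at ``t_on`` in place."""
    xy += vec[None, :] * minimum_jerk_step(t - t_on, dur)[:, None]


def simulate_fixational_gaze(
    schedule: EventSchedule,
    rate_profile: RateProfile,
    noise_sd: float = 0.01,
    seed=0,
    geometry: Optional[GeometryConfig] = None,
    drift_step_sd: float = 0.002,
    drift_bound: float = 1.0,
    recenter_threshold: float = 0.5,
    violation: Optional[str] = None,
    event_kwargs: Optional[dict] = None,
    margin: float = 0.0,
) -> tuple[SampledSeries, list[MicrosaccadeEvent]]:
    """Simulate 500-Hz fixational gaze for one trial.

    Gaze holds on the target with a random-walk drift (clamped to
    ``drift_bound`` cm of the target centre) plus white measurement noise.
    Microsaccades drawn from ``rate_profile`` are injected as smooth
    (minimum-jerk) displacement steps whose peak velocity follows the main
    sequence 1.875·amplitude/duration; when accumulated event displacement
    exceeds ``recenter_threshold`` cm the next event is aimed back at the
    target centre, keeping gaze within the 6-cm fixation window.

    ``violation`` ∈ {fixation_start_late, fixation_end_early, landing_gt_6cm,
    missing_eye} plants one unambiguous exclusion-rule violation.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    rng = _as_rng(seed)
    geometry = geometry or GeometryConfig()
    center = np.asarray(geometry.target_position, dtype=float)
    start = np.asarray(geometry.start_position, dtype=float)
    dt = 0.002
    n = int(math.floor((schedule.t_trial_end + margin) / dt)) + 1
    t = np.arange(n) * dt

    # drift: zero-mean random walk, radially clamped to the fixation bound
    steps = rng.normal(0.0, drift_step_sd, (n, 2))
    steps[0] = 0.0
    drift = np.cumsum(steps, axis=0)
    r = np.hypot(drift[:, 0], drift[:, 1])
    over = r > drift_bound
    if over.any():
        drift[over] *= (drift_bound / r[over])[:, None]

    xy = center[None, :] + drift

    # injected microsaccades
    t0_rel = schedule.t_show_target - schedule.t_go
    t1_rel = schedule.t_trial_end - schedule.t_go
    triples = sample_events(rate_profile, t0_rel, t1_rel, rng, **(event_kwargs or {}))
    events: list[MicrosaccadeEvent] = []
    offset = np.zeros(2)
    for onset_rel, dur, amp in triples:
        onset = onset_rel + schedule.t_go
        if np.hypot(*offset) > recenter_threshold:
            base_angle = math.atan2(-offset[1], -offset[0])
            angle = base_angle + rng.normal(0.0, math.radians(20.0))
        else:
            angle = rng.uniform(0.0, 2 * math.pi)
        vec = amp * np.array([math.cos(angle), math.sin(angle)])
        if np.hypot(*(offset + vec)) > 4.0:
            back = -offset / max(np.hypot(*offset), 1e-9)
            vec = amp * back
        _add_step(xy, t, onset, dur, vec)
        offset = offset + vec
        events.append(
            MicrosaccadeEvent(
                t_onset=onset,
                t_offset=onset + dur,
                amplitude=amp,
                peak_velocity=1.875 * amp / dur,
            )
        )

    missing = np.zeros(n, dtype=bool)
    mid_delay = 0.5 * (schedule.t_show_target + schedule.t_go)
    if violation == "fixation_start_late":
        # gaze begins at the hand start position and arrives on target ~150 ms
        # after target appearance (>= 100 ms => late fixation start)
        away = start - center
        xy += away[None, :] * (1.0 - minimum_jerk_step(t - 0.12, 0.06))[:, None]
    elif violation == "fixation_end_early":
        # gaze departs to the start position 400 ms before the analysis
        # window ends and never returns
        t_leave = schedule.t_trial_end - 0.4
        _add_step(xy, t, t_leave, 0.06, start - center)
    elif violation == "landing_gt_6cm":
        # a large saccade lands 7 cm from the target, then returns
        out = np.array([7.0, 0.0])
        _add_step(xy, t, mid_delay, 0.06, out)
        _add_step(xy, t, mid_delay + 0.16, 0.06, -out)
    elif violation == "missing_eye":
        lost = (t >= mid_delay) & (t < mid_delay + 0.15)
        missing |= lost
    elif violation not in (None, "rt_below_100ms"):
        raise DomainError(f"unknown violation label: {violation}")

    xy = xy + rng.normal(0.0, noise_sd, (n, 2))
    xy[missing] = np.nan
    return SampledSeries(t, xy, 500.0, missing), events


# ---------------------------------------------------------------------------
# hand simulation (1000 Hz)
# ---------------------------------------------------------------------------

def simulate_hand_reach(
    schedule: EventSchedule,
    rt: float = 0.4,
    d: float = 1.36,
    a: float = 20.0,
    noise_sd: float = 0.002,
    seed=0,
    geometry: Optional[GeometryConfig] = None,
    margin: float = 0.0,
) -> tuple[SampledSeries, float, float]:
    """Simulate a 1000-Hz hand series: stationary until ``t_go + rt``, then a
    minimum-jerk reach of amplitude ``a`` toward the target over ``d`` s.

    Returns the series plus the true movement onset and offset times.
    """
    if d <= 0:
        raise DomainError("movement duration must be positive")
    if rt < 0:
        raise DomainError("reaction time must be non-negative")
    rng = _as_rng(seed)
    geometry = geometry or GeometryConfig()
    start = np.asarray(geometry.start_position, dtype=float)
    target = np.asarray(geometry.target_position, dtype=float)
    direction = (target - start) / max(np.linalg.norm(target - start), 1e-12)

    dt = 0.001
    n = int(math.floor((schedule.t_trial_end + margin) / dt)) + 1
    t = np.arange(n) * dt
    t_on = schedule.t_go + rt
    disp = minimum_jerk_step(t - t_on, d) * a
    xy = start[None, :] + direction[None, :] * disp[:, None]
    xy = xy + rng.normal(0.0, noise_sd, (n, 2))
    return SampledSeries(t, xy, 1000.0), t_on, t_on + d


def stationary_hand(schedule: EventSchedule, noise_sd: float = 0.002, seed=0,
                    geometry: Optional[GeometryConfig] = None,
                    margin: float = 0.0) -> SampledSeries:
    """Hand resting at the start position for the whole trial."""
    rng = _as_rng(seed)
    geometry = geometry or GeometryConfig()
    start = np.asarray(geometry.start_position, dtype=float)
    dt = 0.001
    n = int(math.floor((schedule.t_trial_end + margin) / dt)) + 1
    t = np.arange(n) * dt
    xy = start[None, :] + rng.normal(0.0, noise_sd, (n, 2))
    return SampledSeries(t, xy, 1000.0)


# ---------------------------------------------------------------------------
# whole-trial / whole-dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatorConfig:
    """All tunable simulator parameters (defaults are the task's values)."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    delay_range: tuple[float, float] = (1.8, 2.0)
    post_cue_delay: float = 0.3
    cue_hold: float = 0.8
    cursor_duration_range: tuple[float, float] = (1.15, 1.35)
    bow_amplitude: float = 0.25

    reach_amplitude: float = 20.0
    reach_duration_mean: float = 1.36
    reach_duration_sd: float = 0.08
    reach_duration_range: tuple[float, float] = (1.16, 1.56)
    rt_shift: float = 0.1
    rt_median_visible: float = 0.38
    rt_median_invisible: float = 0.45
    rt_log_sd: float = 0.25

    rate_profile: RateProfile = field(default_factory=InhibitionProfile)
    eye_noise_sd: float = 0.01
    drift_step_sd: float = 0.002
    drift_bound: float = 1.0
    hand_noise_sd: float = 0.002

    # in-target rule parameters for the condition-specific endings
    visible_hold: float = 0.5
    invisible_speed_threshold: float = 10.0
    invisible_hold: float = 0.2
    #: recording continues briefly past the rule-defined trial end so the
    #: end event is observable in the recorded trace
    trace_margin: float = 0.1


def _reach_trial_end(cond: Condition, t_go: float, rt: float, d: float,
                     cfg: SimulatorConfig) -> float:
    """Condition-specific ending of a reach, from the noiseless kinematics."""
    a = cfg.reach_amplitude
    if cond is Condition.REACH_VISIBLE:
        # cursor inside the target disc (radius = target radius) for 500 ms
        frac = (a - cfg.geometry.target_diameter_cm / 2.0) / a
        tau_enter = brentq(lambda x: minimum_jerk_step(x, 1.0) - frac, 0.0, 1.0)
        return t_go + rt + tau_enter * d + cfg.visible_hold
    # speed below 10 cm/s for 200 ms, evaluated from the deceleration phase
    v_thr = cfg.invisible_speed_threshold
    peak = 1.875 * a / d
    if peak <= v_thr:
        return t_go + rt + d + cfg.invisible_hold
    tau_v = brentq(
        lambda x: 30 * x**2 * (1 - x) ** 2 - v_thr * d / a, 0.5, 1.0
    )
    return t_go + rt + tau_v * d + cfg.invisible_hold


def generate_trial(
    participant: str,
    trial_index: int,
    condition: Condition,
    cfg: Optional[SimulatorConfig] = None,
    seed=0,
    violation: Optional[str] = None,
) -> TrialRecord:
    """Generate one complete synthetic trial with ground truth."""
    cfg = cfg or SimulatorConfig()
    rng = _as_rng(seed)
    condition = Condition(condition)
    if violation is not None and violation not in VIOLATION_RULES:
        raise DomainError(f"unknown violation label: {violation}")

    t_go = rng.uniform(*cfg.delay_range)
    rt = None
    d = None
    cursor_d = None
    if condition.requires_reach:
        if violation == "rt_below_100ms":
            # zero true RT keeps the measured RT (onset-criterion lag ~0.06·d)
            # unambiguously below the 100-ms rule
            rt = 0.0
        else:
            med = (
                cfg.rt_median_visible
                if condition is Condition.REACH_VISIBLE
                else cfg.rt_median_invisible
            )
            rt = cfg.rt_shift + (med - cfg.rt_shift) * math.exp(
                rng.normal(0.0, cfg.rt_log_sd)
            )
        d = float(
            np.clip(
                rng.normal(cfg.reach_duration_mean, cfg.reach_duration_sd),
                *cfg.reach_duration_range,
            )
        )
        t_end = _reach_trial_end(condition, t_go, rt, d, cfg)
    elif condition is Condition.CURSOR_TRACKING:
        cursor_d = rng.uniform(*cfg.cursor_duration_range)
        t_end = t_go + cfg.post_cue_delay + cursor_d
    else:  # cue monitoring
        t_end = t_go + cfg.post_cue_delay + cfg.cue_hold

    schedule = EventSchedule(
        condition=condition,
        t_show_target=0.0,
        t_go=t_go,
        t_trial_end=t_end,
        post_cue_delay=cfg.post_cue_delay,
        cursor_move_duration=cursor_d,
    )

    # hand
    if condition.requires_reach:
        hand, true_on, true_off = simulate_hand_reach(
            schedule, rt=rt, d=d, a=cfg.reach_amplitude,
            noise_sd=cfg.hand_noise_sd, seed=rng, geometry=cfg.geometry,
            margin=cfg.trace_margin,
        )
    else:
        hand = stationary_hand(
            schedule, noise_sd=cfg.hand_noise_sd, seed=rng,
            geometry=cfg.geometry, margin=cfg.trace_margin,
        )
        # scheduled movement phase stands in for kinematic onset/offset
        true_on = t_go + cfg.post_cue_delay
        true_off = t_end

    # cursor
    if condition is Condition.CURSOR_TRACKING:
        bow_dir = "right" if rng.uniform() < 0.5 else "left"
        move = generate_cursor_trajectory(
            a=cfg.reach_amplitude, d=cursor_d, bow_direction=bow_dir,
            dt=0.001, bow_amplitude=cfg.bow_amplitude,
        )
        start = np.asarray(cfg.geometry.start_position, dtype=float)
        xy = np.tile(start, (hand.n, 1))
        t_move = t_go + cfg.post_cue_delay
        i0 = int(round(t_move / 0.001))
        span = min(move.n, hand.n - i0)
        if span > 0:
            xy[i0 : i0 + span] = start[None, :] + move.xy[:span]
            xy[i0 + span :] = start[None, :] + move.xy[span - 1]
        cursor = SampledSeries(hand.t.copy(), xy, 1000.0)
    elif condition is Condition.REACH_INVISIBLE:
        cursor = None
    else:
        cursor = hand.copy()

    gaze, events = simulate_fixational_gaze(
        schedule,
        cfg.rate_profile,
        noise_sd=cfg.eye_noise_sd,
        seed=rng,
        geometry=cfg.geometry,
        drift_step_sd=cfg.drift_step_sd,
        drift_bound=cfg.drift_bound,
        violation=violation,
        margin=cfg.trace_margin,
    )

    truth = GroundTruth(
        injected_events=events,
        true_hand_onset=true_on,
        true_hand_offset=true_off,
        reaction_time=rt,
        rate_profile=cfg.rate_profile.descriptor(),
        violations=[VIOLATION_RULES[violation]] if violation else [],
    )
    return TrialRecord(
        trial_id=f"{participant}_{condition.value}_{trial_index:03d}",
        participant=participant,
        schedule=schedule,
        gaze=gaze,
        hand=hand,
        cursor=cursor,
        ground_truth=truth,
    )


def generate_dataset(
    cfg: Optional[SimulatorConfig] = None,
    n_participants: int = 17,
    n_trials_per_condition: int = 60,
    seed: int = 0,
    violation_fractions: Optional[dict[str, float]] = None,
) -> list[TrialRecord]:
    """Generate a full four-condition dataset.

    ``violation_fractions`` maps violation labels (see ``VIOLATION_RULES``) to
    the fraction of trials per participant×condition block that plant that
    violation; planted counts are exact (rounded per block) and recorded in
    each trial's ground truth.
    """
    if n_participants < 1 or n_trials_per_condition < 1:
        raise DomainError("counts must be >= 1")
    cfg = cfg or SimulatorConfig()
    violation_fractions = violation_fractions or {}
    for label in violation_fractions:
        if label not in VIOLATION_RULES:
            raise DomainError(f"unknown violation label: {label}")
    master = np.random.SeedSequence(seed)
    trials: list[TrialRecord] = []
    for p in range(n_participants):
        participant = f"P{p + 1:02d}"
        for condition in Condition:
            labels: list[Optional[str]] = []
            for label, frac in violation_fractions.items():
                if label == "rt_below_100ms" and not condition.requires_reach:
                    continue  # RT rule only applies to reach trials
                labels += [label] * int(round(frac * n_trials_per_condition))
            if len(labels) > n_trials_per_condition:
                raise DomainError("violation fractions exceed the trial count")
            labels += [None] * (n_trials_per_condition - len(labels))
            block_ss = master.spawn(1)[0]
            rng = np.random.default_rng(block_ss)
            rng.shuffle(labels)
            for k in range(n_trials_per_condition):
                trials.append(
                    generate_trial(
                        participant,
                        k,
                        condition,
                        cfg,
                        seed=np.random.default_rng(block_ss.spawn(1)[0]),
                        violation=labels[k],
                    )
                )
    return trials
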