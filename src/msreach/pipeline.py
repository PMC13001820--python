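"""End-to-end orchestration: preprocess → detect → segment → exclude → rates.

``analyze_trial`` runs the per-trial chain on one :class:`TrialRecord`;
``analyze_dataset`` applies it to a dataset, applies the exclusion rules,
and builds zone summaries and pooled rate curves; ``run_pipeline`` drives a
full simulated run from a :class:`RunConfig` and writes every intermediate
to disk as delimited text / JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as msio
from .errors import (
    MsreachError,
    NoTrialEndError,
    SegmentationError,
    ValidationError,
)
from .exclusion import TrialFeatures, apply_exclusions
from .handseg import segment_reach, trial_end_reach_invisible, trial_end_reach_visible
from .msdetect import compute_thresholds, detect_microsaccades, moving_window_velocity
from .preprocess import SampledSeries, differentiate, filter_eye, filter_hand, upsample_eye
from .rates import TrialEvents, ZONES, rate_kernel_method, rate_state_method, zone_summary_table
from .stats_report import build_report
from .synth import SimulatorConfig, generate_dataset
from .types import Condition, GeometryConfig, MicrosaccadeEvent, MovementSegment, TrialRecord

logger = logging.getLogger("msreach")

__all__ = ["AnalysisParams", "AnalyzedTrial", "RunConfig",
           "analyze_trial", "analyze_dataset", "run_pipeline"]


@dataclass
class AnalysisParams:
    """Detector / rate-estimator parameters (defaults are the task's values)."""

    lam: float = 5.0
    min_duration: float = 0.040
    velocity_window: int = 5
    kernel_alpha: float = 20.0
    rate_method: str = "state_based"
    fixation_radius_cm: float = 6.0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)


@dataclass
class AnalyzedTrial:
    """Per-trial analysis products feeding exclusion and rate estimation."""

    trial: TrialRecord
    events: list[MicrosaccadeEvent]
    segment: Optional[MovementSegment]
    features: TrialFeatures
    trial_events: TrialEvents


def _slice_series(series: SampledSeries, t0: float, t1: float) -> SampledSeries:
    sel = (series.t >= t0 - 1e-9) & (series.t <= t1 + 1e-9)
    return SampledSeries(series.t[sel], series.xy[sel], series.rate_hz,
                         series.missing[sel])


def analyze_trial(trial: TrialRecord, params: Optional[AnalysisParams] = None) -> AnalyzedTrial:
    """Run preprocessing, detection, segmentation, and feature extraction."""
    params = params or AnalysisParams()
    sched = trial.schedule
    target = np.asarray(params.geometry.target_position, dtype=float)

    # --- hand: filter, differentiate, segment (reach conditions) ---
    hand_f = filter_hand(trial.hand)
    vel = differentiate(hand_f)
    speed = np.hypot(vel.xy[:, 0], vel.xy[:, 1])
    segment = None
    window_end = sched.t_trial_end
    if sched.condition.requires_reach:
        try:
            segment = segment_reach(
                hand_f, sched.t_go,
                y_start=params.geometry.start_position[1],
                y_target=params.geometry.target_position[1],
            )
        except SegmentationError:
            logger.warning("trial %s: hand segmentation failed", trial.trial_id)
        try:
            if sched.condition is Condition.REACH_VISIBLE and trial.cursor is not None:
                window_end = trial_end_reach_visible(
                    trial.cursor, params.geometry.target_position,
                    params.geometry.target_diameter_cm / 2.0,
                )
            elif sched.condition is Condition.REACH_INVISIBLE and segment is not None:
                t_peak = hand_f.t[int(np.argmax(np.where(
                    hand_f.t >= segment.t_onset, speed, -np.inf)))]
                window_end = trial_end_reach_invisible(
                    speed, hand_f.t, t_movement_onset=t_peak
                )
        except NoTrialEndError:
            logger.warning("trial %s: no trial-end event; using schedule",
                           trial.trial_id)
    elif sched.condition is Condition.CUE_MONITORING:
        window_end = sched.t_go + sched.post_cue_delay + 0.8
    window_end = min(window_end, sched.t_trial_end)

    # --- eye: upsample, filter, detect ---
    eye_1000 = upsample_eye(trial.gaze)
    in_window = (eye_1000.t >= sched.t_show_target) & (eye_1000.t <= window_end)
    eye_missing = bool((eye_1000.missing & in_window).any())
    events: list[MicrosaccadeEvent] = []
    fixation_start = fixation_end = None
    if not eye_missing:
        eye_f = filter_eye(eye_1000)
        gaze_vel = moving_window_velocity(eye_f, params.velocity_window)
        thresholds = compute_thresholds(
            _slice_series(gaze_vel, sched.t_show_target, sched.t_trial_end),
            lam=params.lam,
        )
        events = detect_microsaccades(
            gaze_vel, thresholds, min_duration=params.min_duration,
            t_start=sched.t_show_target, t_end=sched.t_trial_end, pos=eye_f,
        )
        dist = np.hypot(eye_f.xy[:, 0] - target[0], eye_f.xy[:, 1] - target[1])
        fix = in_window & (dist <= params.fixation_radius_cm)
        if fix.any():
            idx = np.flatnonzero(fix)
            fixation_start = float(eye_1000.t[idx[0]])
            fixation_end = float(eye_1000.t[idx[-1]])
        landings = [
            float(np.hypot(*(eye_f.xy[int(round(e.t_offset * 1000))] - target)))
            for e in events
        ]
    else:
        landings = []

    features = TrialFeatures(
        trial_id=trial.trial_id,
        condition=sched.condition,
        t_show_target=sched.t_show_target,
        window_end=window_end,
        eye_missing=eye_missing,
        fixation_start=fixation_start,
        fixation_end=fixation_end,
        landing_distances=landings,
        reaction_time=segment.reaction_time if segment is not None else None,
    )

    # movement phase: kinematic for reaches, scheduled for the others
    if sched.condition.requires_reach:
        phase = (
            (segment.t_onset - sched.t_go, segment.t_offset - sched.t_go)
            if segment is not None
            else None
        )
    else:
        phase = (sched.post_cue_delay, sched.t_trial_end - sched.t_go)
    trial_events = TrialEvents(
        t_start=sched.t_show_target - sched.t_go,
        t_end=sched.t_trial_end - sched.t_go,
        onsets=np.array([e.t_onset - sched.t_go for e in events]),
        offsets=np.array([e.t_offset - sched.t_go for e in events]),
        movement_phase=phase,
    )
    return AnalyzedTrial(trial, events, segment, features, trial_events)


@dataclass
class DatasetResults:
    analyzed: list[AnalyzedTrial]
    retained: list[AnalyzedTrial]
    exclusion_report: "object"
    zone_table: pd.DataFrame
    rate_curves: dict[str, "object"]


def analyze_dataset(
    trials: list[TrialRecord],
    params: Optional[AnalysisParams] = None,
) -> DatasetResults:
    """Analyze every trial, apply exclusions, and summarise rates by zone."""
    params = params or AnalysisParams()
    analyzed = [analyze_trial(t, params) for t in trials]
    _, report = apply_exclusions([a.features for a in analyzed])
    retained = [a for a in analyzed if report.reasons[a.trial.trial_id] is None]

    by_cell: dict[tuple[str, str], list[TrialEvents]] = {}
    by_cond: dict[str, list[TrialEvents]] = {}
    for a in retained:
        cell = (a.trial.participant, a.trial.schedule.condition.value)
        by_cell.setdefault(cell, []).append(a.trial_events)
        by_cond.setdefault(cell[1], []).append(a.trial_events)

    zone_table = zone_summary_table(
        by_cell, method=params.rate_method, alpha=params.kernel_alpha
    )
    curves = {}
    for cond, evs in by_cond.items():
        if params.rate_method == "causal_kernel":
            curves[cond] = rate_kernel_method(evs, alpha=params.kernel_alpha)
        else:
            curves[cond] = rate_state_method(evs)
    return DatasetResults(analyzed, retained, report, zone_table, curves)


# ---------------------------------------------------------------------------
# configured runs
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the task's values."""

    seed: int = 1
    n_participants: int = 17
    n_trials_per_condition: int = 60
    violation_fractions: dict = field(default_factory=dict)
    lam: float = 5.0
    min_duration: float = 0.040
    velocity_window: int = 5
    kernel_alpha: float = 20.0
    rate_method: str = "state_based"
    zones: list = field(default_factory=lambda: list(ZONES))
    write_trials: bool = True
    verbosity: int = 1

    def validate(self) -> None:
        problems = []
        if self.lam <= 0:
            problems.append("lam must be positive")
        if self.min_duration <= 0:
            problems.append("min_duration must be positive")
        if self.velocity_window != 5:
            problems.append("velocity_window must be 5")
        if self.kernel_alpha <= 0:
            problems.append("kernel_alpha must be positive")
        if self.n_participants < 1:
            problems.append("n_participants must be >= 1")
        if self.n_trials_per_condition < 1:
            problems.append("n_trials_per_condition must be >= 1")
        if self.rate_method not in ("state_based", "causal_kernel"):
            problems.append("rate_method must be state_based or causal_kernel")
        unknown = [z for z in self.zones if z not in ZONES]
        if unknown:
            problems.append(f"unknown zones: {unknown}")
        if problems:
            raise ValidationError(problems)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError([f"unknown config keys: {sorted(unknown)}"])
        return cls(**mapping)

    def analysis_params(self) -> AnalysisParams:
        return AnalysisParams(
            lam=self.lam,
            min_duration=self.min_duration,
            velocity_window=self.velocity_window,
            kernel_alpha=self.kernel_alpha,
            rate_method=self.rate_method,
        )


def _events_frame(analyzed: list[AnalyzedTrial]) -> pd.DataFrame:
    rows = []
    for a in analyzed:
        for e in a.events:
            rows.append({
                "trial_id": a.trial.trial_id,
                "participant": a.trial.participant,
                "condition": a.trial.schedule.condition.value,
                "t_onset": e.t_onset, "t_offset": e.t_offset,
                "duration": e.duration, "amplitude": e.amplitude,
                "peak_velocity": e.peak_velocity,
            })
    return pd.DataFrame(rows, columns=[
        "trial_id", "participant", "condition", "t_onset", "t_offset",
        "duration", "amplitude", "peak_velocity"])


def _segments_frame(analyzed: list[AnalyzedTrial]) -> pd.DataFrame:
    rows = []
    for a in analyzed:
        if a.segment is None:
            continue
        s = a.segment
        rows.append({
            "trial_id": a.trial.trial_id,
            "participant": a.trial.participant,
            "condition": a.trial.schedule.condition.value,
            "t_onset": s.t_onset, "t_offset": s.t_offset,
            "duration": s.duration, "reaction_time": s.reaction_time,
            "peak_velocity": s.peak_velocity,
            "mid_range_avg_speed": s.mid_range_avg_speed,
        })
    return pd.DataFrame(rows, columns=[
        "trial_id", "participant", "condition", "t_onset", "t_offset",
        "duration", "reaction_time", "peak_velocity", "mid_range_avg_speed"])


def run_pipeline(config: RunConfig, outdir) -> DatasetResults:
    """Simulate, analyze, and report one full run into ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.verbosity:
        logging.basicConfig(level=logging.INFO)

    trials = generate_dataset(
        SimulatorConfig(),
        n_participants=config.n_participants,
        n_trials_per_condition=config.n_trials_per_condition,
        seed=config.seed,
        violation_fractions=config.violation_fractions,
    )
    if config.write_trials:
        msio.write_dataset(trials, outdir / "trials")

    results = analyze_dataset(trials, config.analysis_params())
    _events_frame(results.analyzed).to_csv(outdir / "events.csv", index=False)
    _segments_frame(results.analyzed).to_csv(outdir / "segments.csv", index=False)
    report = results.exclusion_report
    with open(outdir / "exclusion_report.json", "w") as fh:
        json.dump({
            "n_input": report.n_input,
            "n_excluded_by_rule": report.n_excluded_by_rule,
            "n_retained": report.n_retained,
            "reasons": report.reasons,
        }, fh, indent=1)
    for cond, series in results.rate_curves.items():
        pd.DataFrame({"t": series.t, "rate": series.rate,
                      "coverage": series.coverage}).to_csv(
            outdir / f"rate_{cond}.csv", index=False)
    build_report(results.zone_table, results.rate_curves, outdir)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=str)
    return results
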