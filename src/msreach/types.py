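"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import DomainError
from .preprocess import SampledSeries


class Condition(str, Enum):
    """The four task conditions of the go phase."""

    CUE_MONITORING = "cue_monitoring"
    CURSOR_TRACKING = "cursor_tracking"
    REACH_VISIBLE = "reach_visible"
    REACH_INVISIBLE = "reach_invisible"

    @property
    def requires_reach(self) -> bool:
        return self in (Condition.REACH_VISIBLE, Condition.REACH_INVISIBLE)


#: exclusion-rule codes, in the order the rules are applied
RULE_RT_OR_MISSING_EYE = "rt_below_100ms_or_missing_eye"
RULE_FIXATION_START_LATE = "fixation_start_late"
RULE_FIXATION_END_EARLY = "fixation_end_early"
RULE_LANDING_GT_6CM = "landing_gt_6cm"
EXCLUSION_RULES = (
    RULE_RT_OR_MISSING_EYE,
    RULE_FIXATION_START_LATE,
    RULE_FIXATION_END_EARLY,
    RULE_LANDING_GT_6CM,
)


@dataclass
class GeometryConfig:
    """Workspace geometry: 20-cm vertical reach, 37-cm viewing distance."""

    start_position: tuple[float, float] = (0.0, 0.0)
    target_position: tuple[float, float] = (0.0, 20.0)
    target_diameter_cm: float = 2.0
    start_diameter_cm: float = 2.0
    cursor_diameter_cm: float = 1.0
    viewing_distance_cm: float = 37.0

    def __post_init__(self):
        for name in ("target_diameter_cm", "start_diameter_cm", "cursor_diameter_cm"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.viewing_distance_cm <= 0:
            raise DomainError("viewing_distance_cm must be positive")

    @property
    def reach_amplitude_cm(self) -> float:
        dx = self.target_position[0] - self.start_position[0]
        dy = self.target_position[1] - self.start_position[1]
        return float(np.hypot(dx, dy))

    def visual_angle_deg(self, extent_cm: float = 1.0) -> float:
        """Visual angle subtended by ``extent_cm`` at the viewing distance."""
        return float(
            np.degrees(2.0 * np.arctan(0.5 * extent_cm / self.viewing_distance_cm))
        )


@dataclass
class EventSchedule:
    """Per-trial event times (seconds from target appearance).

    The fixation target appears at ``t_show_target``, turns into the go cue
    after a 1.8–2.0-s delay, and the trial ends at the condition-specific
    ``t_trial_end``.
    """

    condition: Condition
    t_show_target: float
    t_go: float
    t_trial_end: float
    post_cue_delay: float = 0.3
    cursor_move_duration: Optional[float] = None

    def __post_init__(self):
        self.condition = Condition(self.condition)
        if not self.t_show_target < self.t_go:
            raise DomainError("t_show_target must precede t_go")
        if not self.t_go < self.t_trial_end:
            raise DomainError("t_go must precede t_trial_end")
        d = self.delay_duration
        if not (1.8 - 1e-9 <= d <= 2.0 + 1e-9):
            raise DomainError(f"delay duration {d:.3f} s outside [1.8, 2.0]")
        if self.condition is Condition.CURSOR_TRACKING:
            if self.cursor_move_duration is None:
                raise DomainError("cursor_tracking requires cursor_move_duration")
            if not (1.15 - 1e-9 <= self.cursor_move_duration <= 1.35 + 1e-9):
                raise DomainError("cursor_move_duration outside [1.15, 1.35]")

    @property
    def delay_duration(self) -> float:
        return self.t_go - self.t_show_target


@dataclass
class MicrosaccadeEvent:
    """A detected or injected microsaccade.

    ``amplitude`` is the Euclidean onset→offset gaze displacement;
    ``peak_velocity`` the maximum 2-D speed between onset and offset.
    """

    t_onset: float
    t_offset: float
    amplitude: float
    peak_velocity: float

    def __post_init__(self):
        if not self.t_offset > self.t_onset:
            raise DomainError("t_offset must exceed t_onset")
        if self.amplitude < 0:
            raise DomainError("amplitude must be non-negative")

    @property
    def duration(self) -> float:
        return self.t_offset - self.t_onset


@dataclass
class MovementSegment:
    """Kinematic summary of one hand reach (or scheduled movement phase)."""

    t_onset: float
    t_offset: float
    peak_velocity: float
    reaction_time: Optional[float] = None
    mid_range_avg_speed: Optional[float] = None

    def __post_init__(self):
        if not self.t_onset < self.t_offset:
            raise DomainError("movement onset must precede offset")

    @property
    def duration(self) -> float:
        return self.t_offset - self.t_onset


@dataclass
class GroundTruth:
    """Simulator-side truth attached to a synthetic trial."""

    injected_events: list[MicrosaccadeEvent] = field(default_factory=list)
    true_hand_onset: Optional[float] = None
    true_hand_offset: Optional[float] = None
    reaction_time: Optional[float] = None
    rate_profile: dict = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)


@dataclass
class TrialRecord:
    """One trial: raw gaze (500 Hz), hand (1000 Hz), optional cursor, schedule."""

    trial_id: str
    participant: str
    schedule: EventSchedule
    gaze: SampledSeries
    hand: SampledSeries
    cursor: Optional[SampledSeries] = None
    ground_truth: Optional[GroundTruth] = None
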