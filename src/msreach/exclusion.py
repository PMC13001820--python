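"""Trial exclusion: the four instruction-violation filters.

Rules are applied sequentially, and a trial is counted under the first rule
it violates, so per-rule counts sum to the total number of excluded trials:

1. hand reaction time below 100 ms, or missing eye data;
2. target fixation started too late (≥ 100 ms after target appearance);
3. target fixation ended too early (≥ 100 ms before the cursor reached the
   target / the pre-determined window end);
4. a saccade landed more than 6 cm away from the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import PipelineOrderError
from .types import (
    Condition,
    EXCLUSION_RULES,
    RULE_FIXATION_END_EARLY,
    RULE_FIXATION_START_LATE,
    RULE_LANDING_GT_6CM,
    RULE_RT_OR_MISSING_EYE,
)

__all__ = ["TrialFeatures", "ExclusionReport", "apply_exclusions"]

#: thresholds of the four rules
RT_MIN = 0.1
FIXATION_START_LATE_S = 0.1
FIXATION_END_EARLY_S = 0.1
LANDING_MAX_CM = 6.0


@dataclass
class TrialFeatures:
    """Derived per-trial quantities the exclusion rules inspect.

    Times are absolute trial times (seconds).  ``window_end`` is the time the
    cursor reached the target (reaches / tracking) or the pre-determined
    window end (cue monitoring); ``landing_distances`` are the distances of
    detected saccade landings (event offsets) from the target centre.
    """

    trial_id: str
    condition: Condition
    t_show_target: float
    window_end: float
    eye_missing: bool
    fixation_start: Optional[float]
    fixation_end: Optional[float]
    landing_distances: Sequence[float] = field(default_factory=tuple)
    reaction_time: Optional[float] = None


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts plus per-trial reason codes."""

    n_input: int
    n_excluded_by_rule: dict[str, int]
    n_retained: int
    reasons: dict[str, Optional[str]]

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_rule.values())


def _violated_rule(f: TrialFeatures) -> Optional[str]:
    if f.condition.requires_reach and f.reaction_time is None and not f.eye_missing:
        raise PipelineOrderError(
            f"trial {f.trial_id}: reach trial lacks a reaction time; run "
            "segmentation before exclusion"
        )
    if f.eye_missing or (
        f.condition.requires_reach and f.reaction_time < RT_MIN
    ):
        return RULE_RT_OR_MISSING_EYE
    if (
        f.fixation_start is None
        or f.fixation_start - f.t_show_target >= FIXATION_START_LATE_S
    ):
        return RULE_FIXATION_START_LATE
    if (
        f.fixation_end is None
        or f.window_end - f.fixation_end >= FIXATION_END_EARLY_S
    ):
        return RULE_FIXATION_END_EARLY
    if any(d > LANDING_MAX_CM for d in f.landing_distances):
        return RULE_LANDING_GT_6CM
    return None


def apply_exclusions(
    features: Sequence[TrialFeatures],
) -> tuple[list[TrialFeatures], ExclusionReport]:
    """Apply the four rules in order; return retained trials and the report."""
    counts = {rule: 0 for rule in EXCLUSION_RULES}
    reasons: dict[str, Optional[str]] = {}
    retained = []
    for f in features:
        rule = _violated_rule(f)
        reasons[f.trial_id] = rule
        if rule is None:
            retained.append(f)
        else:
            counts[rule] += 1
    report = ExclusionReport(
        n_input=len(features),
        n_excluded_by_rule=counts,
        n_retained=len(retained),
        reasons=reasons,
    )
    return retained, report
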