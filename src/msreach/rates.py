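"""Time-varying microsaccade-rate estimation and zone summaries.

Two estimators, both aligned to the go cue (t = 0) on a 1-ms grid:

* state-based — the per-millisecond fraction of trials whose binary
  microsaccade state (1 while an event is ongoing) is set, divided by the
  average event duration;
* causal-kernel — per-millisecond onset counts across trials convolved with
  the unit-mass causal kernel ω(τ) = α²·τ·e^(−ατ), τ ≥ 0.

Trials of unequal length contribute only at times their window covers; the
per-time normalisation uses the count of covering trials.  Named analysis
zones (windows relative to the go cue) summarise each participant×condition
rate curve; the movement zone is the per-trial movement phase, summarised as
total onsets divided by total phase duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "TrialEvents",
    "RateSeries",
    "ZoneDefinition",
    "ZONES",
    "rate_state_method",
    "rate_kernel_method",
    "zone_average",
    "movement_zone_rate",
    "zone_summary_table",
]

DT = 0.001  #: rate-series resolution (s)


@dataclass
class TrialEvents:
    """One trial's detected (or injected) events, go-cue-aligned.

    ``t_start``/``t_end`` bound the trial's analysis window and
    ``onsets``/``offsets`` the event times, all in seconds relative to the
    go cue.  ``movement_phase`` is the (start, end) of the condition-specific
    movement phase, when defined.
    """

    t_start: float
    t_end: float
    onsets: np.ndarray
    offsets: np.ndarray
    movement_phase: Optional[tuple[float, float]] = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.onsets.shape != self.offsets.shape:
            raise DomainError("onsets and offsets must have equal length")
        if not self.t_start < self.t_end:
            raise DomainError("t_start must precede t_end")


@dataclass
class ZoneDefinition:
    """A named analysis window (start, end) in seconds relative to the go cue."""

    name: str
    window: Optional[tuple[float, float]]  # None => per-trial movement phase


#: the named zones (windows relative to the go cue)
ZONES: dict[str, ZoneDefinition] = {
    "initial_fixation": ZoneDefinition("initial_fixation", (-1.75, -1.65)),
    "pre_cue_250": ZoneDefinition("pre_cue_250", (-0.25, 0.0)),
    "pre_cue_375": ZoneDefinition("pre_cue_375", (-0.375, 0.0)),
    "pre_cue_500": ZoneDefinition("pre_cue_500", (-0.5, 0.0)),
    "post_inhibition": ZoneDefinition("post_inhibition", (0.3, 0.8)),
    "pre_cue_inhibition": ZoneDefinition("pre_cue_inhibition", (-0.1, 0.0)),
    "post_cue_inhibition": ZoneDefinition("post_cue_inhibition", (0.15, 0.25)),
    "movement": ZoneDefinition("movement", None),
}


@dataclass
class RateSeries:
    """A go-cue-aligned microsaccade-rate time course (Hz)."""

    t: np.ndarray
    rate: np.ndarray
    coverage: np.ndarray  # trials covering each time point
    n_trials: int
    method: str


def _grid(trials: Sequence[TrialEvents]) -> np.ndarray:
    t0 = min(tr.t_start for tr in trials)
    t1 = max(tr.t_end for tr in trials)
    n = int(round((t1 - t0) / DT)) + 1
    return t0 + np.arange(n) * DT


def _coverage(trials: Sequence[TrialEvents], t: np.ndarray) -> np.ndarray:
    cov = np.zeros(t.size)
    t0 = t[0]
    for tr in trials:
        i0 = max(int(round((tr.t_start - t0) / DT)), 0)
        i1 = min(int(round((tr.t_end - t0) / DT)) + 1, t.size)
        cov[i0:i1] += 1
    return cov


def mean_event_duration(trials: Sequence[TrialEvents]) -> float:
    """Average event duration across all trials (s)."""
    durs = np.concatenate([tr.offsets - tr.onsets for tr in trials]) \
        if trials else np.array([])
    if durs.size == 0:
        raise DomainError("no events: cannot estimate the mean duration")
    return float(durs.mean())


def rate_state_method(
    trials: Sequence[TrialEvents],
    mean_duration: Optional[float] = None,
) -> RateSeries:
    """Binary-state rate estimate.

    ``mean_duration`` defaults to the dataset's own mean event duration (as
    the rate is computed from the same detections).  If no trial contains an
    event the rate is identically zero.
    """
    if not trials:
        raise DomainError("need at least one trial")
    if mean_duration is not None and mean_duration <= 0:
        raise DomainError("mean event duration must be positive")
    t = _grid(trials)
    cov = _coverage(trials, t)
    state_sum = np.zeros(t.size)
    t0 = t[0]
    any_events = False
    for tr in trials:
        for on, off in zip(tr.onsets, tr.offsets):
            i0 = max(int(round((on - t0) / DT)), 0)
            i1 = min(int(round((off - t0) / DT)) + 1, t.size)
            if i1 > i0:
                state_sum[i0:i1] += 1
                any_events = True
    if not any_events:
        return RateSeries(t, np.zeros(t.size), cov, len(trials), "state_based")
    if mean_duration is None:
        mean_duration = mean_event_duration(trials)
    rate = np.zeros(t.size)
    np.divide(state_sum, cov * mean_duration, out=rate, where=cov > 0)
    return RateSeries(t, rate, cov, len(trials), "state_based")


def causal_kernel(alpha: float, dt: float = DT) -> np.ndarray:
    """Discretised unit-mass causal kernel ω(τ) = α²·τ·e^(−ατ) (1/s)."""
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    tau = np.arange(0.0, 10.0 / alpha, dt)
    w = alpha**2 * tau * np.exp(-alpha * tau)
    return w / (w.sum() * dt)  # exact unit mass on the grid


def rate_kernel_method(
    trials: Sequence[TrialEvents],
    alpha: float = 20.0,
) -> RateSeries:
    """Causal-kernel rate estimate (default α = 1/0.050 s⁻¹).

    Onset counts per millisecond are normalised by the per-time trial
    coverage and convolved with the unit-mass kernel, so the rate integrates
    to onsets-per-trial over an isolated window.
    """
    if not trials:
        raise DomainError("need at least one trial")
    t = _grid(trials)
    cov = _coverage(trials, t)
    counts = np.zeros(t.size)
    t0 = t[0]
    for tr in trials:
        idx = np.round((tr.onsets - t0) / DT).astype(int)
        idx = idx[(idx >= 0) & (idx < t.size)]
        np.add.at(counts, idx, 1.0)
    density = np.zeros(t.size)
    np.divide(counts, cov, out=density, where=cov > 0)
    w = causal_kernel(alpha)
    rate = np.convolve(density, w)[: t.size]
    return RateSeries(t, rate, cov, len(trials), "causal_kernel")


def zone_average(series: RateSeries, zone: ZoneDefinition) -> float:
    """Arithmetic mean of the rate over a zone's samples ([start, end))."""
    if zone.window is None:
        raise DomainError("the movement zone is summarised per trial; "
                          "use movement_zone_rate")
    start, end = zone.window
    if start < series.t[0] - 1e-9 or end > series.t[-1] + DT + 1e-9:
        raise DomainError(f"zone {zone.name} outside the series support")
    mask = (series.t >= start - 1e-9) & (series.t < end - 1e-9)
    if not mask.any():
        raise DomainError(f"zone {zone.name} contains no samples")
    return float(series.rate[mask].mean())


def movement_zone_rate(trials: Sequence[TrialEvents]) -> float:
    """Total onset count within movement phases ÷ total phase duration (Hz)."""
    total_onsets = 0
    total_duration = 0.0
    for tr in trials:
        if tr.movement_phase is None:
            continue
        lo, hi = tr.movement_phase
        total_onsets += int(np.sum((tr.onsets >= lo) & (tr.onsets < hi)))
        total_duration += hi - lo
    if total_duration <= 0:
        raise DomainError("zero total movement-phase duration")
    return total_onsets / total_duration


def zone_summary_table(
    trials_by_cell: dict[tuple[str, str], Sequence[TrialEvents]],
    zones: Optional[Sequence[str]] = None,
    method: str = "state_based",
    alpha: float = 20.0,
    mean_duration: Optional[float] = None,
) -> pd.DataFrame:
    """Per participant×condition average rate in each named zone.

    ``trials_by_cell`` maps (participant, condition) to that cell's trials.
    Returns a long DataFrame with columns participant, condition, zone,
    mean_rate (Hz).  The movement zone uses the pooled onsets/duration ratio;
    window zones average the cell's rate curve (window zones whose support is
    not covered by the cell are skipped).
    """
    zones = list(zones) if zones is not None else list(ZONES)
    rows = []
    for (participant, condition), trials in trials_by_cell.items():
        if not trials:
            continue
        if method == "state_based":
            series = rate_state_method(trials, mean_duration=mean_duration)
        elif method == "causal_kernel":
            series = rate_kernel_method(trials, alpha=alpha)
        else:
            raise DomainError(f"unknown rate method: {method}")
        for name in zones:
            zone = ZONES[name]
            if zone.window is None:
                if any(tr.movement_phase is not None for tr in trials):
                    value = movement_zone_rate(trials)
                else:
                    continue
            else:
                try:
                    value = zone_average(series, zone)
                except DomainError:
                    continue
            rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    "zone": name,
                    "mean_rate": value,
                }
            )
    return pd.DataFrame(rows, columns=["participant", "condition", "zone", "mean_rate"])
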