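"""Hand-movement segmentation and condition-specific trial endings.

Movement onset is the last upward crossing of 5% of peak speed before the
speed peak at which the hand is also accelerating at ≥ 5% of the peak
acceleration; offset is the first downward crossing after the peak at which
the hand is decelerating at ≥ 5% of the peak deceleration.  Trial-end rules:
reach-visible trials end after the cursor has been inside the target disc
for 500 ms; reach-invisible trials end after hand speed has stayed below
10 cm/s for 200 ms (evaluated after movement onset).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import DomainError, NoTrialEndError, SegmentationError
from .preprocess import SampledSeries
from .types import MovementSegment

__all__ = [
    "find_movement_onset_offset",
    "mid_range_avg_speed",
    "trial_end_reach_visible",
    "trial_end_reach_invisible",
    "segment_reach",
]

#: onset/offset criterion as a fraction of peak speed / peak acceleration
CRITERION_FRACTION = 0.05
#: reaches slower than this peak speed (cm/s) are treated as "no movement"
MIN_PEAK_SPEED = 5.0


def find_movement_onset_offset(
    speed: np.ndarray,
    t: np.ndarray,
    acc: Optional[np.ndarray] = None,
    t_search_start: Optional[float] = None,
    fraction: float = CRITERION_FRACTION,
    min_peak_speed: float = MIN_PEAK_SPEED,
) -> tuple[float, float]:
    """Locate movement onset and offset with the combined 5% velocity +
    acceleration criterion.

    ``speed`` is the hand speed (cm/s) and ``acc`` its time derivative
    (computed by central differences if omitted).  The search may be
    restricted to ``t >= t_search_start`` (e.g. the go cue).
    """
    speed = np.asarray(speed, dtype=float)
    t = np.asarray(t, dtype=float)
    if speed.shape != t.shape:
        raise DomainError("speed and t must have the same shape")
    if acc is None:
        acc = np.gradient(speed, t)
    else:
        acc = np.asarray(acc, dtype=float)

    lo = 0 if t_search_start is None else int(np.searchsorted(t, t_search_start))
    s, a_ = speed[lo:], acc[lo:]
    if s.size < 3:
        raise SegmentationError("search window too short")
    p = int(np.argmax(s))
    v_peak = s[p]
    if v_peak < min_peak_speed:
        raise SegmentationError(
            f"peak speed {v_peak:.2f} cm/s below {min_peak_speed} cm/s: "
            "no movement detected"
        )
    thr = fraction * v_peak

    # onset: last upward crossing before the peak with sufficient acceleration
    a_peak_pre = a_[: p + 1].max() if p > 0 else 0.0
    up = np.flatnonzero((s[1 : p + 1] >= thr) & (s[:p] < thr)) + 1
    up = up[a_[up] >= fraction * a_peak_pre]
    if up.size == 0:
        raise SegmentationError(
            f"no onset crossing of {thr:.2f} cm/s with acceleration "
            f">= {fraction * a_peak_pre:.2f} cm/s^2 before the speed peak"
        )
    i_on = int(up[-1])

    # offset: first downward crossing after the peak with sufficient deceleration
    d_peak_post = (-a_[p:]).max()
    down = np.flatnonzero((s[p + 1 :] < thr) & (s[p:-1] >= thr)) + p + 1
    down = down[-a_[down] >= fraction * d_peak_post]
    if down.size == 0:
        raise SegmentationError(
            f"no offset crossing of {thr:.2f} cm/s with deceleration "
            f">= {fraction * d_peak_post:.2f} cm/s^2 after the speed peak"
        )
    i_off = int(down[0])
    return float(t[lo + i_on]), float(t[lo + i_off])


def mid_range_avg_speed(
    t: np.ndarray,
    y: np.ndarray,
    speed: np.ndarray,
    y_start: float,
    y_target: float,
) -> float:
    """Average hand speed between the first crossings of 25% and 75% of the
    y distance to the target (the task's speed-feedback metric; goal
    20 cm/s)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    speed = np.asarray(speed, dtype=float)
    span = y_target - y_start
    if span == 0:
        raise DomainError("y_start equals y_target")
    frac = (y - y_start) / span
    marks = []
    for q in (0.25, 0.75):
        hit = np.flatnonzero(frac >= q)
        if hit.size == 0:
            raise DomainError(f"hand never crossed {q:.0%} of the y distance")
        marks.append(hit[0])
    i25, i75 = marks
    if i75 <= i25:
        raise DomainError("75% mark not after 25% mark")
    return float(np.trapezoid(speed[i25 : i75 + 1], t[i25 : i75 + 1])
                 / (t[i75] - t[i25]))


def _first_hold_run(t: np.ndarray, inside: np.ndarray, hold: float) -> float:
    """End time of the first run of True samples spanning at least ``hold``."""
    padded = np.concatenate([[False], inside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        if t[i1 - 1] - t[i0] >= hold - 1e-9:
            return float(t[i0] + hold)
    raise NoTrialEndError(f"no {hold * 1e3:.0f}-ms qualifying run found")


def trial_end_reach_visible(
    cursor: SampledSeries,
    target_position: tuple[float, float],
    target_radius: float,
    hold: float = 0.5,
) -> float:
    """Trial end: cursor inside the target disc for ``hold`` seconds.

    A dip into the target shorter than ``hold`` does not end the trial; the
    run restarts at re-entry.
    """
    target = np.asarray(target_position, dtype=float)
    dist = np.hypot(cursor.xy[:, 0] - target[0], cursor.xy[:, 1] - target[1])
    return _first_hold_run(cursor.t, dist <= target_radius, hold)


def trial_end_reach_invisible(
    speed: np.ndarray,
    t: np.ndarray,
    t_movement_onset: float,
    threshold: float = 10.0,
    hold: float = 0.2,
) -> float:
    """Trial end: hand speed below ``threshold`` cm/s for ``hold`` seconds,
    evaluated after movement onset (its speed peak, in practice)."""
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if t_movement_onset is None:
        raise NoTrialEndError("no movement onset: cannot apply the speed rule")
    after = t >= t_movement_onset
    if not after.any():
        raise NoTrialEndError("movement onset beyond the trace")
    return _first_hold_run(t[after], speed[after] < threshold, hold)


def segment_reach(
    hand_filtered: SampledSeries,
    t_go: float,
    y_start: float,
    y_target: float,
) -> MovementSegment:
    """Full kinematic summary of a reach from the filtered hand series."""
    v = np.gradient(hand_filtered.xy, hand_filtered.dt, axis=0)
    speed = np.hypot(v[:, 0], v[:, 1])
    t_on, t_off = find_movement_onset_offset(
        speed, hand_filtered.t, t_search_start=t_go
    )
    sel = (hand_filtered.t >= t_on) & (hand_filtered.t <= t_off)
    peak = float(speed[sel].max())
    try:
        mid = mid_range_avg_speed(
            hand_filtered.t, hand_filtered.xy[:, 1], speed, y_start, y_target
        )
    except DomainError:
        mid = None
    return MovementSegment(
        t_onset=t_on,
        t_offset=t_off,
        peak_velocity=peak,
        reaction_time=t_on - t_go,
        mid_range_avg_speed=mid,
    )
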