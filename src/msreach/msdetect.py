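"""Velocity-threshold microsaccade detection.

Events are detected in 2-D velocity space with per-axis thresholds set at
λ (default 5) multiples of a median-based standard deviation,
σ = sqrt(median(v²) − median(v)²), forming an elliptic criterion
(vx/ηx)² + (vy/ηy)² > 1.  A candidate event is a maximal run of samples
strictly outside the ellipse; runs shorter than 40 samples (40 ms at
1000 Hz) are discarded.  Onset is the first sample outside the ellipse,
offset the last.

The gaze velocity used for detection is a 5-sample moving-window central
difference, the convention of velocity-based saccade detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateThresholdError, DomainError
from .preprocess import SampledSeries
from .types import MicrosaccadeEvent

__all__ = [
    "VelocityThresholds",
    "moving_window_velocity",
    "compute_thresholds",
    "detect_microsaccades",
    "characterize_event",
]


@dataclass
class VelocityThresholds:
    """Per-axis elliptic velocity thresholds η = λ·σ (cm/s)."""

    eta_x: float
    eta_y: float
    lam: float
    sigma_x: float
    sigma_y: float

    def __post_init__(self):
        if self.eta_x <= 0 or self.eta_y <= 0:
            raise DomainError("thresholds must be positive")


def moving_window_velocity(series: SampledSeries, window: int = 5) -> SampledSeries:
    """5-sample moving-window central-difference velocity (cm/s).

    v[i] = (x[i+2] + x[i+1] − x[i−1] − x[i−2]) · rate / 6; the two samples at
    each end fall back to plain central/one-sided differences.
    """
    if window != 5:
        raise DomainError("only the 5-sample window is implemented")
    xy = series.xy
    n = series.n
    if n < window:
        raise DomainError("series shorter than the velocity window")
    v = np.gradient(xy, series.dt, axis=0)
    v[2:-2] = (xy[4:] + xy[3:-1] - xy[1:-3] - xy[:-4]) * (series.rate_hz / 6.0)
    return SampledSeries(series.t.copy(), v, series.rate_hz, series.missing.copy())


def compute_thresholds(vel: SampledSeries, lam: float = 5.0) -> VelocityThresholds:
    """Median-based-SD elliptic thresholds from a 2-D velocity series."""
    if lam <= 0:
        raise DomainError("lambda must be positive")
    valid = ~vel.missing
    if valid.sum() < 5:
        raise DomainError("need at least 5 valid velocity samples per axis")
    sigmas = []
    for axis, name in ((0, "x"), (1, "y")):
        v = vel.xy[valid, axis]
        var = np.median(v**2) - np.median(v) ** 2
        sigma = float(np.sqrt(max(var, 0.0)))
        if sigma <= 0:
            raise DegenerateThresholdError(name)
        sigmas.append(sigma)
    return VelocityThresholds(
        eta_x=lam * sigmas[0],
        eta_y=lam * sigmas[1],
        lam=lam,
        sigma_x=sigmas[0],
        sigma_y=sigmas[1],
    )


def detect_microsaccades(
    vel: SampledSeries,
    thresholds: VelocityThresholds,
    min_duration: float = 0.040,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
    pos: Optional[SampledSeries] = None,
) -> list[MicrosaccadeEvent]:
    """Detect microsaccades as maximal suprathreshold runs.

    Detection is restricted to [t_start, t_end] (the target-on → trial-end
    window in the pipeline).  A run qualifies if it spans at least
    ``min_duration × rate`` samples.  If ``pos`` is given, amplitudes are the
    Euclidean onset→offset displacement of that position series; otherwise
    amplitude is integrated from the velocity.
    """
    t = vel.t
    mask = np.ones(vel.n, dtype=bool)
    if t_start is not None:
        mask &= t >= t_start - 1e-9
    if t_end is not None:
        mask &= t <= t_end + 1e-9
    n_win = int(mask.sum())
    min_samples = int(round(min_duration * vel.rate_hz))
    if n_win < min_samples:
        warnings.warn("detection window shorter than the minimum event duration")
        return []

    vx, vy = vel.xy[:, 0], vel.xy[:, 1]
    with np.errstate(invalid="ignore"):
        outside = (vx / thresholds.eta_x) ** 2 + (vy / thresholds.eta_y) ** 2 > 1.0
    outside &= mask & ~vel.missing

    # maximal runs of outside samples
    padded = np.concatenate([[False], outside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]  # [start, stop) index pairs
    events = []
    for i0, i1 in zip(starts, stops):
        if i1 - i0 < min_samples:
            continue
        t_on, t_off = t[i0], t[i1 - 1]
        if pos is not None:
            amp, _, peak = characterize_event(pos, vel, t_on, t_off)
        else:
            speed = np.hypot(vx[i0:i1], vy[i0:i1])
            peak = float(speed.max())
            disp = np.trapezoid(vel.xy[i0:i1], dx=vel.dt, axis=0)
            amp = float(np.hypot(*disp))
        events.append(
            MicrosaccadeEvent(
                t_onset=float(t_on),
                t_offset=float(t_off),
                amplitude=amp,
                peak_velocity=peak,
            )
        )
    return events


def characterize_event(
    pos: SampledSeries,
    vel: SampledSeries,
    t_onset: float,
    t_offset: float,
) -> tuple[float, float, float]:
    """(amplitude, duration, peak velocity) of an event.

    Amplitude is the Euclidean distance between the gaze positions at onset
    and offset; peak velocity the maximum 2-D speed over [onset, offset].
    """
    if not (pos.t[0] - 1e-9 <= t_onset < t_offset <= pos.t[-1] + 1e-9):
        raise DomainError("onset/offset outside the series")
    i_on = int(round((t_onset - pos.t[0]) * pos.rate_hz))
    i_off = int(round((t_offset - pos.t[0]) * pos.rate_hz))
    amp = float(np.linalg.norm(pos.xy[i_off] - pos.xy[i_on]))
    speed = np.hypot(vel.xy[i_on : i_off + 1, 0], vel.xy[i_on : i_off + 1, 1])
    peak = float(np.nanmax(speed))
    return amp, t_offset - t_onset, peak
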