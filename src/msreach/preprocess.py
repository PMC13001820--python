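"""Shared time-base and filtering for gaze and hand signals.

Raw gaze is recorded at 500 Hz and hand position at 1000 Hz.  Analysis runs on
a common 1000-Hz grid: gaze is linearly upsampled, then both signals are
low-pass filtered with zero-phase (forward–backward) Butterworth filters —
second order / 15 Hz for the eye, third order / 10 Hz for the hand.
Derivatives are central differences on the filtered positions.

Missing gaze samples are carried as NaN plus a boolean mask; upsampling never
interpolates across a missing sample, and filtering refuses spans that contain
gaps (callers route such trials to the exclusion stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import FormatError

__all__ = [
    "SampledSeries",
    "upsample_eye",
    "filter_eye",
    "filter_hand",
    "differentiate",
]

#: maximum reflective padding (samples at 1000 Hz) used by the zero-phase filters
_MAX_PADLEN = 1000


@dataclass
class SampledSeries:
    """A uniformly sampled 2-D position (or derivative) time series.

    Attributes
    ----------
    t : (n,) array of sample times in seconds, strictly increasing with a
        constant step of ``1 / rate_hz``.
    xy : (n, 2) array of x/y values in cm (or cm/s, cm/s² for derivatives).
        NaN wherever ``missing`` is True.
    rate_hz : sampling rate in Hz.
    missing : (n,) boolean mask of missing samples.
    """

    t: np.ndarray
    xy: np.ndarray
    rate_hz: float
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise FormatError(f"xy must have shape (n, 2), got {self.xy.shape}")
        if self.t.shape[0] != self.xy.shape[0]:
            raise FormatError("t and xy lengths differ")
        if self.missing is None:
            self.missing = ~np.isfinite(self.xy).all(axis=1)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        dt = np.diff(self.t)
        if self.t.size >= 2:
            step = 1.0 / self.rate_hz
            if not np.allclose(dt, step, rtol=0, atol=step * 1e-3):
                raise FormatError("non-uniform sample timing")
        valid = ~self.missing
        if not np.isfinite(self.xy[valid]).all():
            raise FormatError("non-finite values outside the missing mask")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def n(self) -> int:
        return self.t.shape[0]

    def copy(self) -> "SampledSeries":
        return SampledSeries(
            self.t.copy(), self.xy.copy(), self.rate_hz, self.missing.copy()
        )


def upsample_eye(series: SampledSeries) -> SampledSeries:
    """Upsample a 500-Hz gaze series onto the 1000-Hz hand time base.

    Linear interpolation between adjacent native samples; original sample
    instants are preserved exactly.  An inserted midpoint is missing whenever
    either neighbouring native sample is missing, so missing runs propagate
    and are never bridged.
    """
    if series.rate_hz != 500:
        raise FormatError(f"expected a 500-Hz series, got {series.rate_hz} Hz")
    n = series.n
    if n < 2:
        raise FormatError("need at least two samples to upsample")
    t_new = series.t[0] + np.arange(2 * n - 1) / 1000.0
    xy = np.full((2 * n - 1, 2), np.nan)
    xy[::2] = series.xy
    # midpoint of a pair is NaN if either neighbour is NaN: no bridging
    xy[1::2] = 0.5 * (series.xy[:-1] + series.xy[1:])
    missing = np.zeros(2 * n - 1, dtype=bool)
    missing[::2] = series.missing
    missing[1::2] = series.missing[:-1] | series.missing[1:]
    xy[missing] = np.nan
    return SampledSeries(t_new, xy, 1000.0, missing)


def _zero_phase_lowpass(series: SampledSeries, order: int, cutoff_hz: float) -> SampledSeries:
    if series.missing.any():
        raise FormatError(
            "series contains missing samples; split into contiguous valid "
            "spans (or exclude the trial) before filtering"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=series.rate_hz)
    padlen = min(series.n - 1, _MAX_PADLEN)
    xy = filtfilt(b, a, series.xy, axis=0, padtype="even", padlen=padlen)
    return SampledSeries(series.t.copy(), xy, series.rate_hz, series.missing.copy())


def filter_hand(series: SampledSeries) -> SampledSeries:
    """Third-order, zero-phase, 10-Hz low-pass Butterworth filter."""
    return _zero_phase_lowpass(series, order=3, cutoff_hz=10.0)


def filter_eye(series: SampledSeries) -> SampledSeries:
    """Second-order, zero-phase, 15-Hz low-pass Butterworth filter."""
    return _zero_phase_lowpass(series, order=2, cutoff_hz=15.0)


def differentiate(series: SampledSeries, order: int = 1) -> SampledSeries:
    """Differentiate a position series (order 1: velocity, 2: acceleration).

    Central differences in the interior, one-sided at the endpoints; output
    units are cm/s (order 1) or cm/s² (order 2).
    """
    if order not in (1, 2):
        raise FormatError("order must be 1 or 2")
    if series.n < 3:
        raise FormatError("series shorter than the difference stencil")
    out = series.xy
    for _ in range(order):
        out = np.gradient(out, series.dt, axis=0)
    return SampledSeries(series.t.copy(), out, series.rate_hz, series.missing.copy())
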