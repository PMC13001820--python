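"""Independent brute-force oracles used by the tests.

These deliberately re-derive results with the slowest, most literal
implementation possible (per-sample Python loops, closed forms, root
finding) so they share no code with the package paths they check.
"""

import numpy as np
from scipy.optimize import brentq


def brute_force_detect(vx, vy, t, eta_x, eta_y, min_samples=40,
                       t_start=None, t_end=None):
    """Literal per-sample scan of the elliptic criterion + run-length filter.

    Returns (onset_index, offset_index) pairs of maximal runs of samples
    strictly outside the ellipse, at least ``min_samples`` long.
    """
    events = []
    run = []
    for i in range(len(t)):
        in_window = (t_start is None or t[i] >= t_start - 1e-9) and (
            t_end is None or t[i] <= t_end + 1e-9
        )
        outside = in_window and (
            (vx[i] / eta_x) ** 2 + (vy[i] / eta_y) ** 2 > 1.0
        )
        if outside:
            run.append(i)
        else:
            if len(run) >= min_samples:
                events.append((run[0], run[-1]))
            run = []
    if len(run) >= min_samples:
        events.append((run[0], run[-1]))
    return events


def median_sd(v):
    """sqrt(median(v^2) - median(v)^2), computed independently."""
    v = np.asarray(v, dtype=float)
    return float(np.sqrt(np.median(v**2) - np.median(v) ** 2))


def minimum_jerk_onset_fraction(fraction=0.05):
    """Root of 30 tau^2 (1-tau)^2 = fraction * 1.875 on the rising flank."""
    return brentq(
        lambda x: 30 * x**2 * (1 - x) ** 2 - fraction * 1.875, 1e-6, 0.5
    )


def minimum_jerk_distance_fraction_time(q):
    """tau at which the minimum-jerk displacement reaches fraction ``q``."""
    return brentq(lambda x: 10 * x**3 - 15 * x**4 + 6 * x**5 - q, 0.0, 1.0)


def smooth_random_trace(rng, n, dt=0.001, n_events=0):
    """A smooth random 2-D velocity trace (cm/s), optionally with injected
    high-velocity bursts, for detector-equivalence checks."""
    v = rng.normal(0.0, 1.0, (n, 2))
    win = np.hanning(21)
    win /= win.sum()
    for k in range(2):
        v[:, k] = np.convolve(v[:, k], win, mode="same")
    v += rng.normal(0.0, 0.05, (n, 2))  # white floor keeps the spread positive
    for _ in range(n_events):
        dur = rng.integers(30, 90)
        i0 = rng.integers(0, max(n - dur, 1))
        angle = rng.uniform(0, 2 * np.pi)
        peak = rng.uniform(10, 40)
        burst = peak * np.sin(np.linspace(0, np.pi, dur)) ** 2
        v[i0 : i0 + dur, 0] += burst * np.cos(angle)
        v[i0 : i0 + dur, 1] += burst * np.sin(angle)
    t = np.arange(n) * dt
    return t, v
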