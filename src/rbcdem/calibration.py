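"""Period detection and per-period averaging of oscillating cell signals.

Resolved single-cell simulations produce time traces of drag coefficient and
deformation index that oscillate with the cell's flow mode (tumbling, tank
treading or mixtures); all modes are periodic, so a single representative
value per (Re, r*) campaign point is obtained by averaging each measured
quantity over whole periods.  The period is detected from the first dominant
peak of the unbiased autocorrelation; at least three whole periods of data are
required before an average is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = ["SignalTrace", "PeriodNotFoundError", "detect_period", "period_average"]

#: minimum normalized autocorrelation for a peak to count as a period
SIGNIFICANCE = 0.2
#: minimum number of whole periods required for averaging
MIN_PERIODS = 3


class PeriodNotFoundError(ValueError):
    """No significant periodicity in the trace."""


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled signal (t strictly increasing, constant spacing)."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape or len(t) < 8:
            raise ValueError("need matching 1-D arrays of at least 8 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
            raise ValueError("samples must be uniformly spaced in time")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])


def _autocorrelation(y: np.ndarray) -> np.ndarray:
    """Unbiased, normalized autocorrelation r[k], k = 0..n//2."""
    y = y - y.mean()
    n = len(y)
    var = float(y @ y) / n
    if var == 0:
        return np.zeros(n // 2 + 1)
    full = np.correlate(y, y, mode="full")[n - 1:]
    k = np.arange(len(full))
    r = full / (n - k) / var
    return r[: n // 2 + 1]


def detect_period(trace: SignalTrace, significance: float = SIGNIFICANCE) -> float:
    """Dominant period from the first significant autocorrelation peak.

    The peak location is refined by parabolic interpolation, giving
    sub-sample resolution.  Raises :class:`PeriodNotFoundError` for constant
    or aperiodic signals.
    """
    r = _autocorrelation(trace.y)
    if np.all(r == 0):
        raise PeriodNotFoundError("constant signal has no period")
    peaks, _ = find_peaks(r[1:], height=significance)
    if len(peaks) == 0:
        raise PeriodNotFoundError("no autocorrelation peak above the significance threshold")
    k = int(peaks[0]) + 1
    lag = float(k)
    if 1 <= k < len(r) - 1:
        denom = r[k - 1] - 2.0 * r[k] + r[k + 1]
        if denom != 0:
            lag += 0.5 * (r[k - 1] - r[k + 1]) / denom
    return lag * trace.dt


def period_average(trace: SignalTrace, period: float):
    """Mean of the signal over each whole period, and the mean of those means.

    Partial trailing periods are discarded; fewer than three whole periods is
    an error (a steady-state average needs at least that much data).
    Returns ``(per_period_means, grand_mean)``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    n_whole = int(np.floor(trace.span / period + 1e-9))
    if n_whole < MIN_PERIODS:
        raise ValueError(f"trace spans only {n_whole} whole periods; need >= {MIN_PERIODS}")
    m = 256
    means = np.empty(n_whole)
    for k in range(n_whole):
        ts = trace.t[0] + k * period + (np.arange(m) + 0.5) * (period / m)
        means[k] = np.interp(ts, trace.t, trace.y).mean()
    return means, float(means.mean())
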