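"""Dynamic-window smoothing: respiratory- and heart-rate extraction.

The method smooths a period's data series with a centered moving average
whose half-width adapts to the latest rate estimate: W = floor(Fs/(4r)) for
respiration (r in Hz) and w = floor(Fs/(4h)) for heartbeat, i.e. the window
spans roughly half the oscillation period.  The smoothed series keeps the
respiratory waveform; counting its peaks gives the respiratory rate.  The
smoothed series is then scaled by an amplification coefficient alpha
(estimated from the sample sums around the respiratory peaks) and subtracted
from the original series, leaving the far weaker heartbeat component, which
is smoothed once more with the heart half-window and peak-counted to give
heart rate.

Edge samples of the moving average use symmetric growing windows (2n-1
points at the left edge, 2(N-n)+1 at the right), so a constant series is
reproduced exactly everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .errors import DegenerateSignalError, ParameterError, WindowError
from .signal_model import PeriodWindow

# Physiological band edges (Hz): sleep respiration stays below 0.5 Hz,
# heartbeat below 3 Hz; these set the minimum peak spacing for counting.
RESP_MAX_HZ = 0.5
HEART_MAX_HZ = 3.0

# State clamps applied after each window's estimate; they keep the adaptive
# half-windows bounded (a missed window cannot drive W or w to absurd sizes).
RESP_CLAMP = (0.05, 1.0)
HEART_CLAMP = (0.5, 3.5)

DEFAULT_PROMINENCE_FRAC = 0.25


@dataclass(frozen=True)
class RateState:
    """Latest respiratory (r) and heart (h) rates in Hz driving W and w.

    Initial values: r = 0.5 Hz (sleep respiration stays below 30/min, so
    W >= 50 at 100 Hz) and h = 2 Hz (sleep heart rate below 120/min).
    """

    r: float = 0.5
    h: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.r <= RESP_CLAMP[1]:
            raise ParameterError(f"respiratory rate state {self.r} Hz out of range")
        if not 0 < self.h <= HEART_CLAMP[1]:
            raise ParameterError(f"heart rate state {self.h} Hz out of range")


@dataclass(frozen=True)
class SmoothingParams:
    """Sampling rate and the half-width L used for alpha estimation.

    L must stay far below the respiratory half-window W (enforced as
    L < W/4 at use time; L is shrunk when a clamped W makes that tight).
    """

    fs: float
    L: int = 10

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.L < 1:
            raise ParameterError("L must be >= 1")


@dataclass(frozen=True)
class RateEstimate:
    """Per-period detection output."""

    rate_per_min: float
    rate_hz: float
    peak_indices: np.ndarray
    window_used: int
    valid: bool = True

    @classmethod
    def invalid(cls, window_used: int = 0) -> "RateEstimate":
        return cls(
            rate_per_min=float("nan"),
            rate_hz=float("nan"),
            peak_indices=np.array([], dtype=int),
            window_used=window_used,
            valid=False,
        )


def half_window(fs: float, rate: float) -> int:
    """Adaptive half-window floor(fs / (4*rate)), at least 1 sample."""
    if rate <= 0:
        raise ParameterError(f"rate must be positive, got {rate}")
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    return max(1, math.floor(fs / (4.0 * rate)))


def smooth(x: np.ndarray | PeriodWindow, W: int) -> np.ndarray:
    """Centered moving average with half-window W and symmetric edge windows.

    Interior samples (W < n <= N-W, 1-based) are means over 2W+1 points; the
    left edge (n <= W) uses the growing window of 2n-1 points centered on n;
    the right edge uses 2(N-n)+1 points.  Requires N >= 2W+1.
    """
    if isinstance(x, PeriodWindow):
        x = x.values
    x = np.asarray(x, dtype=float)
    n = x.size
    if W < 1:
        raise ParameterError(f"half-window must be >= 1, got {W}")
    if n < 2 * W + 1:
        raise WindowError(
            f"series of length {n} cannot take half-window {W} (need N >= {2 * W + 1}); "
            "use a shorter window or a longer period"
        )
    c = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    j = np.arange(W, n - W)
    out[W : n - W] = (c[j + W + 1] - c[j - W]) / (2 * W + 1)
    jl = np.arange(W)
    out[:W] = c[2 * jl + 1] / (2 * jl + 1)
    jr = np.arange(n - W, n)
    out[n - W :] = (c[n] - c[2 * jr + 1 - n]) / (2 * (n - 1 - jr) + 1)
    return out


def estimate_alpha(x: np.ndarray, xs: np.ndarray, peak: int, L: int) -> float:
    """Amplification coefficient: ratio of sample sums of x and xs over
    the 2L+1 samples around a peak of the smoothed series."""
    x = np.asarray(x, dtype=float)
    xs = np.asarray(xs, dtype=float)
    if x.shape != xs.shape:
        raise ParameterError("x and xs must have equal length")
    if not (peak - L >= 0 and peak + L < x.size):
        raise ParameterError(f"peak {peak} +- L={L} falls outside the series")
    denom = float(xs[peak - L : peak + L + 1].sum())
    if abs(denom) < 1e-12:
        raise DegenerateSignalError(
            "smoothed-series sum around the peak is ~0 (centered or flat signal); "
            "add the series minimum as an offset and retry"
        )
    return float(x[peak - L : peak + L + 1].sum()) / denom


def residual(x: np.ndarray, xs: np.ndarray, alpha: float) -> np.ndarray:
    """Respiration-removed series y(n) = x(n) - alpha * xs(n)."""
    x = np.asarray(x, dtype=float)
    xs = np.asarray(xs, dtype=float)
    if x.shape != xs.shape:
        raise ParameterError("x and xs must have equal length")
    return x - alpha * xs


def find_peaks(
    series: np.ndarray,
    min_distance: int,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> np.ndarray:
    """Local maxima separated by >= min_distance samples whose prominence
    exceeds prominence_frac x (95th - 5th percentile span); of conflicting
    pairs, the higher peak wins."""
    if min_distance < 1:
        raise ParameterError("min_distance must be >= 1")
    if not 0 < prominence_frac < 1:
        raise ParameterError("prominence_frac must lie in (0, 1)")
    series = np.asarray(series, dtype=float)
    span = float(np.percentile(series, 95) - np.percentile(series, 5))
    # a span at float-noise scale means the series is constant for all
    # practical purposes (e.g. the detail bands of a flat signal)
    if span <= 1e-12:
        return np.array([], dtype=int)
    peaks, _ = _scipy_find_peaks(
        series, distance=min_distance, prominence=prominence_frac * span
    )
    return peaks


def _clamped_half_window(fs: float, rate: float, n: int) -> int:
    """half_window clipped so the moving average fits the series."""
    return min(half_window(fs, rate), max(1, (n - 1) // 2))


# Plausibility gate for heart estimates: a true beat train is nearly
# periodic (2-5% beat-to-beat jitter during sleep), while peaks found in a
# heartbeat-free residual are respiratory leakage or noise wiggles with
# either an implausible rate or irregular spacing.  Thresholds sit midway
# between the two regimes (real trains: interval MAD/median <= ~0.05,
# spurious: >= ~0.18).
HEART_PLAUSIBLE_HZ = (0.5, 3.5)
HEART_INTERVAL_MAD_MAX = 0.12


def beat_train_plausible(peaks: np.ndarray, period_s: float) -> bool:
    """True when peak count and spacing look like a heartbeat train."""
    peaks = np.asarray(peaks)
    if peaks.size < 4:
        return False
    rate_hz = peaks.size / period_s
    if not HEART_PLAUSIBLE_HZ[0] <= rate_hz <= HEART_PLAUSIBLE_HZ[1]:
        return False
    intervals = np.diff(peaks)
    med = float(np.median(intervals))
    if med <= 0:
        return False
    return float(np.median(np.abs(intervals - med))) / med <= HEART_INTERVAL_MAD_MAX


def respiratory_rate(
    x: PeriodWindow,
    state: RateState,
    params: SmoothingParams,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> tuple[RateEstimate, RateState, np.ndarray]:
    """Respiratory rate of one occupied period via dynamic smoothing.

    Returns the estimate, the updated rate state, and the smoothed series
    (needed downstream by :func:`heart_rate`).  A zero-peak window yields an
    invalid estimate and leaves the state unchanged.
    """
    W = _clamped_half_window(params.fs, state.r, x.n)
    xs = smooth(x.values, W)
    min_distance = max(1, math.floor(params.fs / (2 * RESP_MAX_HZ)))
    peaks = find_peaks(xs, min_distance, prominence_frac)
    if peaks.size == 0:
        return RateEstimate.invalid(W), state, xs
    rate_hz = peaks.size / x.period_s
    est = RateEstimate(
        rate_per_min=rate_hz * 60.0,
        rate_hz=rate_hz,
        peak_indices=peaks,
        window_used=W,
    )
    new_state = replace(state, r=float(np.clip(rate_hz, *RESP_CLAMP)))
    return est, new_state, xs


def heart_rate(
    x: PeriodWindow,
    resp_smoothed: np.ndarray,
    state: RateState,
    params: SmoothingParams,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    resp_peaks: Optional[Sequence[int]] = None,
) -> tuple[RateEstimate, RateState]:
    """Heart rate of one period after respiration removal.

    alpha is estimated at every detected respiratory peak (median over
    peaks) and the scaled smoothed series subtracted; the residual is
    smoothed with the heart half-window w and peak-counted.

    The amplitude-ratio sums are taken on the mean-removed window: the
    coefficient's purpose is to undo the moving average's attenuation of the
    breathing oscillation, and only on a mean-free series does the ratio of
    sums around a peak equal that attenuation factor.  On the raw series the
    baseline offset (the static posture pressure, ~1.5 V) dominates both sums
    and biases the ratio toward 1, leaving a respiratory residual of up to
    ~30% of the breathing amplitude that can swamp the far weaker heartbeat.
    """
    xv = x.values
    if resp_peaks is None:
        min_distance = max(1, math.floor(params.fs / (2 * RESP_MAX_HZ)))
        resp_peaks = find_peaks(resp_smoothed, min_distance, prominence_frac)
    resp_peaks = np.asarray(resp_peaks, dtype=int)
    W = _clamped_half_window(params.fs, state.r, x.n)
    L = min(params.L, max(1, (W - 1) // 4))
    mean = float(xv.mean())
    xc = xv - mean
    xsc = resp_smoothed - mean
    alphas = []
    for k in resp_peaks:
        if k - L < 0 or k + L >= xv.size:
            continue
        try:
            alphas.append(estimate_alpha(xc, xsc, int(k), L))
        except DegenerateSignalError:
            # flat around this peak; re-anchor above zero and retry
            offset = 1.0 + abs(float(xc.min()))
            alphas.append(estimate_alpha(xc + offset, xsc + offset, int(k), L))
    if not alphas:
        return RateEstimate.invalid(), state
    alpha = float(np.median(alphas))
    y = residual(xv, resp_smoothed, alpha)
    w = _clamped_half_window(params.fs, state.h, x.n)
    y_smooth = smooth(y, w)
    min_distance = max(1, math.floor(params.fs / (2 * HEART_MAX_HZ)))
    peaks = find_peaks(y_smooth, min_distance, prominence_frac)
    if not beat_train_plausible(peaks, x.period_s):
        return RateEstimate.invalid(w), state
    rate_hz = peaks.size / x.period_s
    est = RateEstimate(
        rate_per_min=rate_hz * 60.0,
        rate_hz=rate_hz,
        peak_indices=peaks,
        window_used=w,
    )
    new_state = replace(state, h=float(np.clip(rate_hz, *HEART_CLAMP)))
    return est, new_state


def accuracy(measured: float, true: float) -> float:
    """Rate accuracy in percent: 100 * (1 - |measured - true| / true),
    floored at 0."""
    if true <= 0:
        raise ParameterError(f"true rate must be positive, got {true}")
    return max(0.0, 100.0 * (1.0 - abs(measured - true) / true))
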