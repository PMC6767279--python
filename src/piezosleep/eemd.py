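"""Empirical mode decomposition (EMD) and its ensemble variant (EEMD).

EMD sifts a series into intrinsic mode functions (IMFs), high frequency
first: at each sift step the mean of the cubic-spline upper and lower
envelopes is subtracted, and sifting stops when the normalized squared
difference between successive iterates drops to 0.2 or an iteration cap is
hit.  Subtracting each finished IMF from the running residual and repeating
until too few extrema remain yields the decomposition
x(n) = sum_k IMF_k(n) + R(n), which holds to numerical precision.

EEMD mitigates mode mixing by averaging the IMFs of many EMD runs on
noise-perturbed copies of the input.  Rate extraction assigns each averaged
IMF its dominant Fourier frequency and sums the IMFs falling in the
respiratory (0.2-0.5 Hz) or heartbeat (0.8-3 Hz) band before peak counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .errors import ParameterError
from .signal_model import PeriodWindow
from .smoothing import (
    DEFAULT_PROMINENCE_FRAC,
    HEART_MAX_HZ,
    RESP_MAX_HZ,
    RateEstimate,
    beat_train_plausible,
    find_peaks,
)

SIFT_SD_THRESHOLD = 0.2
DEFAULT_MAX_ITER = 100
DEFAULT_ENSEMBLE = 50
DEFAULT_NOISE_SD_FRAC = 0.2
RESP_BAND = (0.2, 0.5)
HEART_BAND = (0.8, 3.0)
_MAX_IMFS = 24


@dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs (high to low frequency), residual, and sift iteration counts."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_counts: list[int]

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of the interior samples."""
    d = np.diff(x)
    maxima = np.where((d[:-1] > 0) & (d[1:] < 0))[0] + 1
    minima = np.where((d[:-1] < 0) & (d[1:] > 0))[0] + 1
    return maxima, minima


def _mirrored_spline(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through extrema, with the two nearest extrema mirrored
    about each boundary to tame end swings."""
    left_idx = (-idx[:2][::-1]).tolist()
    left_vals = vals[:2][::-1].tolist()
    right_idx = (2 * (n - 1) - idx[-2:][::-1]).tolist()
    right_vals = vals[-2:][::-1].tolist()
    all_idx = np.array(left_idx + idx.tolist() + right_idx, dtype=float)
    all_vals = np.array(left_vals + vals.tolist() + right_vals, dtype=float)
    all_idx, keep = np.unique(all_idx, return_index=True)
    all_vals = all_vals[keep]
    return CubicSpline(all_idx, all_vals)(np.arange(n))


def envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of the cubic-spline upper and lower envelopes, or None when the
    series has fewer than two maxima or two minima (extrema deficit, which
    terminates the decomposition rather than raising)."""
    x = np.asarray(x, dtype=float)
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    return (upper + lower) / 2.0


def sift(x: np.ndarray, max_iter: int = DEFAULT_MAX_ITER) -> tuple[np.ndarray | None, int]:
    """Extract one IMF by repeated envelope-mean subtraction.

    Stops when the normalized squared difference between successive iterates
    falls to SIFT_SD_THRESHOLD (a 1e-12 guard protects zero denominators) or
    after ``max_iter`` iterations.  Returns (None, 0) on extrema deficit.
    """
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    m = envelope_mean(x)
    if m is None:
        return None, 0
    h = np.asarray(x, dtype=float) - m
    iters = 1
    while iters < max_iter:
        m = envelope_mean(h)
        if m is None:
            break
        h_new = h - m
        sd = float(np.sum((h - h_new) ** 2 / (h**2 + 1e-12)))
        h = h_new
        iters += 1
        if sd <= SIFT_SD_THRESHOLD:
            break
    return h, iters


def emd(x: np.ndarray, max_iter: int = DEFAULT_MAX_ITER) -> IMFSet:
    """Full decomposition: sift IMFs off the residual until extrema deficit."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ParameterError(f"series too short for EMD (n={x.size} < 16)")
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    r = x.copy()
    while len(imfs) < _MAX_IMFS:
        imf, iters = sift(r, max_iter)
        if imf is None:
            break
        imfs.append(imf)
        counts.append(iters)
        r = r - imf
    return IMFSet(imfs=imfs, residual=r, sift_counts=counts)


def eemd(
    x: np.ndarray,
    ensemble: int = DEFAULT_ENSEMBLE,
    noise_sd_frac: float = DEFAULT_NOISE_SD_FRAC,
    seed: int | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
) -> IMFSet:
    """Ensemble-averaged EMD over noise-perturbed copies of the input.

    Added noise has standard deviation ``noise_sd_frac * sd(x)``.  IMFs are
    aligned by index across ensemble members, shorter sets zero-padded; the
    result is deterministic for a fixed seed.
    """
    if ensemble < 1:
        raise ParameterError("ensemble size must be >= 1")
    x = np.asarray(x, dtype=float)
    noise_sd = noise_sd_frac * float(x.std())
    if ensemble == 1 and noise_sd == 0:
        return emd(x, max_iter)
    rng = np.random.default_rng(seed)
    all_imfs: list[list[np.ndarray]] = []
    all_resid: list[np.ndarray] = []
    all_counts: list[list[int]] = []
    for _ in range(ensemble):
        noisy = x + rng.normal(0.0, noise_sd, size=x.size) if noise_sd > 0 else x
        dec = emd(noisy, max_iter)
        all_imfs.append(dec.imfs)
        all_resid.append(dec.residual)
        all_counts.append(dec.sift_counts)
    max_m = max(len(s) for s in all_imfs)
    mean_imfs = []
    mean_counts = []
    for k in range(max_m):
        stack = [s[k] if k < len(s) else np.zeros_like(x) for s in all_imfs]
        mean_imfs.append(np.mean(stack, axis=0))
        iters = [c[k] for c in all_counts if k < len(c)]
        mean_counts.append(int(round(np.mean(iters))))
    return IMFSet(
        imfs=mean_imfs,
        residual=np.mean(all_resid, axis=0),
        sift_counts=mean_counts,
    )


def dominant_frequency(series: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the largest non-DC Fourier magnitude bin."""
    series = np.asarray(series, dtype=float)
    mags = np.abs(np.fft.rfft(series))
    freqs = np.fft.rfftfreq(series.size, d=1.0 / fs)
    if mags.size < 2:
        return 0.0
    return float(freqs[1:][np.argmax(mags[1:])])


def eemd_rates(
    x: PeriodWindow,
    ensemble: int = DEFAULT_ENSEMBLE,
    noise_sd_frac: float = DEFAULT_NOISE_SD_FRAC,
    seed: int | None = None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[RateEstimate, RateEstimate]:
    """Respiratory and heart rate from band-matched IMF sums.

    Each IMF is assigned its dominant Fourier frequency; IMFs in 0.2-0.5 Hz
    sum to the respiratory series, IMFs in 0.8-3 Hz to the heartbeat series.
    A band with no IMF yields an invalid estimate.
    """
    dec = eemd(x.values, ensemble, noise_sd_frac, seed, max_iter)
    resp_series = np.zeros(x.n)
    heart_series = np.zeros(x.n)
    n_resp = n_heart = 0
    for imf in dec.imfs:
        f = dominant_frequency(imf, x.fs)
        if RESP_BAND[0] <= f <= RESP_BAND[1]:
            resp_series += imf
            n_resp += 1
        elif HEART_BAND[0] <= f <= HEART_BAND[1]:
            heart_series += imf
            n_heart += 1

    def _rate(series: np.ndarray, count: int, max_hz: float, gate: bool = False) -> RateEstimate:
        if count == 0:
            return RateEstimate.invalid()
        min_distance = max(1, math.floor(x.fs / (2 * max_hz)))
        peaks = find_peaks(series, min_distance, prominence_frac)
        if peaks.size == 0 or (gate and not beat_train_plausible(peaks, x.period_s)):
            return RateEstimate.invalid()
        rate_hz = peaks.size / x.period_s
        return RateEstimate(
            rate_per_min=rate_hz * 60.0,
            rate_hz=rate_hz,
            peak_indices=peaks,
            window_used=0,
        )

    # A heartbeat reconstructed from band-limited IMFs is an oscillatory
    # packet (one complex per beat whose carrier swings twice); counting
    # carrier peaks double-counts beats, so heart peaks are counted on the
    # analytic-signal envelope, which has one bump per beat.
    heart_env = np.abs(hilbert(heart_series)) if n_heart else heart_series
    return (
        _rate(resp_series, n_resp, RESP_MAX_HZ),
        _rate(heart_env, n_heart, HEART_MAX_HZ, gate=True),
    )
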