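"""Wavelet-analysis baseline: multilevel band decomposition and rate extraction.

The cascaded two-band (Mallat) decomposition splits the signal into dyadic
frequency layers; layer i occupies (Fs/2^(i+1), Fs/2^i).  At Fs = 100 Hz and
10 levels, layers 7 (0.39-0.78 Hz) and 8 (0.19-0.39 Hz) bracket sleep
respiration, while layers 4-6 cover the heartbeat band.  Rates are read off
the band reconstructions by peak counting; four basis wavelets (db5, db6,
sym6, coif4) are reconstructed independently and their counts combined by
median.

Layer-i reconstruction uses the detail (band-pass) coefficients d_i, whose
frequency support matches the stated band edges; boundary handling is
symmetric (half-point) signal extension throughout, so results are
deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pywt

from .errors import ParameterError
from .smoothing import (
    DEFAULT_PROMINENCE_FRAC,
    HEART_MAX_HZ,
    RESP_MAX_HZ,
    RateEstimate,
    beat_train_plausible,
    find_peaks,
)
from .signal_model import PeriodWindow

WAVELETS = ("db5", "db6", "sym6", "coif4")
N_LEVELS = 10
RESP_LAYERS = frozenset({7, 8})
HEART_LAYERS = frozenset({4, 5, 6})
_MODE = "symmetric"


@dataclass(frozen=True)
class FrequencyBand:
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ParameterError(f"invalid band ({self.f_low}, {self.f_high})")


@dataclass(frozen=True)
class WaveletDecomposition:
    """10-level multilevel decomposition of one period window.

    ``coeffs`` is the pywt.wavedec layout: [a_levels, d_levels, ..., d_1].
    """

    wavelet_name: str
    coeffs: list
    n: int
    fs: float
    levels: int = N_LEVELS


def band_of_layer(i: int, fs: float) -> FrequencyBand:
    """Frequency band (fs/2^(i+1), fs/2^i) of decomposition layer i."""
    if i < 1:
        raise ParameterError(f"layer index must be >= 1, got {i}")
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    return FrequencyBand(f_low=fs / 2 ** (i + 1), f_high=fs / 2**i)


def decompose(x: PeriodWindow, wavelet_name: str) -> WaveletDecomposition:
    """10-level decomposition of the window with the named wavelet."""
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ParameterError(f"unknown wavelet {wavelet_name!r}")
    with warnings.catch_warnings():
        # 10 levels can exceed pywt's advisory maximum for short windows;
        # deep levels just carry very short coefficient vectors.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x.values, wavelet_name, mode=_MODE, level=N_LEVELS)
    return WaveletDecomposition(
        wavelet_name=wavelet_name, coeffs=coeffs, n=x.n, fs=x.fs
    )


def reconstruct_layers(
    dec: WaveletDecomposition,
    layers: Iterable[int],
    include_approximation: bool = False,
) -> np.ndarray:
    """Length-N series containing only the selected detail layers' content.

    ``layers`` are 1-based layer indices (1 = highest frequency band).  With
    ``include_approximation`` the deepest low-pass residue is kept as well,
    which together with layers {1..levels} restores the original series.
    """
    layers = set(layers)
    if not layers and not include_approximation:
        raise ParameterError("at least one layer must be selected")
    if not layers <= set(range(1, dec.levels + 1)):
        raise ParameterError(f"layers must lie in 1..{dec.levels}, got {sorted(layers)}")
    kept = [
        c if include_approximation else np.zeros_like(c) for c in dec.coeffs[:1]
    ]
    for pos in range(1, len(dec.coeffs)):
        layer_idx = dec.levels + 1 - pos  # coeffs[1] is d_levels, coeffs[-1] is d_1
        c = dec.coeffs[pos]
        kept.append(c if layer_idx in layers else np.zeros_like(c))
    rec = pywt.waverec(kept, dec.wavelet_name, mode=_MODE)
    return rec[: dec.n]


def reconstruct_all(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse transform from all coefficients (perfect reconstruction)."""
    return pywt.waverec(dec.coeffs, dec.wavelet_name, mode=_MODE)[: dec.n]


def _band_rate(
    x: PeriodWindow,
    layers: frozenset[int],
    max_hz: float,
    prominence_frac: float,
    require_beat_train: bool = False,
) -> RateEstimate:
    min_distance = max(1, math.floor(x.fs / (2 * max_hz)))
    # a band whose amplitude is at float-noise scale relative to the input
    # carries no signal (e.g. any detail band of a flat window)
    band_floor = 1e-10 * max(1.0, float(np.abs(x.values).max()))
    counts = []
    peak_sets = []
    for name in WAVELETS:
        dec = decompose(x, name)
        band = reconstruct_layers(dec, layers)
        if float(np.percentile(band, 95) - np.percentile(band, 5)) <= band_floor:
            continue
        peaks = find_peaks(band, min_distance, prominence_frac)
        if require_beat_train and not beat_train_plausible(peaks, x.period_s):
            continue
        if peaks.size:
            counts.append(peaks.size)
            peak_sets.append(peaks)
    if not counts:
        return RateEstimate.invalid()
    rate_hz = float(np.median(counts)) / x.period_s
    representative = peak_sets[int(np.argsort(counts)[len(counts) // 2])]
    return RateEstimate(
        rate_per_min=rate_hz * 60.0,
        rate_hz=rate_hz,
        peak_indices=representative,
        window_used=0,
    )


def wavelet_respiratory_rate(
    x: PeriodWindow, prominence_frac: float = DEFAULT_PROMINENCE_FRAC
) -> RateEstimate:
    """Respiratory rate from the layer {7, 8} band reconstructions,
    median over the four basis wavelets."""
    return _band_rate(x, RESP_LAYERS, RESP_MAX_HZ, prominence_frac)


def wavelet_heart_rate(
    x: PeriodWindow, prominence_frac: float = DEFAULT_PROMINENCE_FRAC
) -> RateEstimate:
    """Heart rate from the layer {4, 5, 6} band reconstructions,
    median over the basis wavelets whose peak trains pass the beat
    plausibility gate."""
    return _band_rate(x, HEART_LAYERS, HEART_MAX_HZ, prominence_frac, require_beat_train=True)
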