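"""Seeded generator of 18-channel mattress recordings with ground truth.

The simulator emulates the signal structure the detectors assume: on each
channel, a baseline offset plus a spatially attenuated physiological
component (respiration as a period- and amplitude-jittered sinusoid at
0.2-0.5 Hz; heartbeat as a much weaker train of smooth biphasic pulses at
0.8-2 Hz), with mains interference, broadband noise, and optional movement
bursts on top.  Channel gains fall off geometrically with grid distance from
the chest cell, so the nearest sensor carries the strongest vitals, which is
what variance-based channel selection exploits.

The ground truth records, per analysis period, the scheduled rates,
occupancy, chest region, and turnover flags, standing in for the reference
instruments a bedside study would use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.signal.windows import tukey

from .errors import AlignmentError, ConfigError
from .occupancy import ChannelVariances
from .signal_model import N_CHANNELS, Recording, SensorLayout
from .smoothing import accuracy

RESP_RATE_BAND = (12.0, 30.0)  # breaths/min during sleep
HEART_RATE_BAND = (48.0, 120.0)  # beats/min during sleep
PERIOD_JITTER_FRAC = 0.05  # +-5% per-cycle respiratory period jitter
AMP_JITTER_FRAC = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Scene description for one simulated recording.

    ``occupancy_schedule`` is a list of non-overlapping
    ``(start_s, end_s, chest_position)`` intervals; when omitted, the bed is
    occupied for the whole duration at ``chest_position``.  ``movement_events``
    are ``(time_s, duration_s, amplitude)`` artifact bursts.
    """

    duration_s: float = 60.0
    fs: float = 100.0
    resp_rate_per_min: float = 18.0
    resp_amplitude: float = 0.5
    heart_rate_per_min: float = 75.0
    heart_to_resp_ratio: float = 0.12
    heart_pulse_width_s: float = 0.08
    mains_freq: float = 50.0
    mains_amplitude: float = 0.02
    white_noise_sd: float = 0.01
    baseline_offset: float = 1.5
    chest_position: tuple[int, int] = (0, 3)
    gain_decay_per_cell: float = 0.5
    occupancy_schedule: Optional[tuple[tuple[float, float, tuple[int, int]], ...]] = None
    movement_events: tuple[tuple[float, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigError("duration and fs must be positive")
        if not RESP_RATE_BAND[0] <= self.resp_rate_per_min <= RESP_RATE_BAND[1]:
            raise ConfigError(
                f"respiratory rate {self.resp_rate_per_min}/min outside sleep band {RESP_RATE_BAND}"
            )
        if not HEART_RATE_BAND[0] <= self.heart_rate_per_min <= HEART_RATE_BAND[1]:
            raise ConfigError(
                f"heart rate {self.heart_rate_per_min}/min outside sleep band {HEART_RATE_BAND}"
            )
        for name in (
            "resp_amplitude",
            "heart_to_resp_ratio",
            "mains_amplitude",
            "white_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        sched = self.schedule
        for (s0, e0, _), (s1, e1, _) in zip(sched, sched[1:]):
            if e0 > s1:
                raise ConfigError(f"occupancy intervals overlap: ({s0},{e0}) and ({s1},{e1})")
        for s, e, _ in sched:
            if not 0 <= s < e:
                raise ConfigError(f"invalid occupancy interval ({s}, {e})")

    @property
    def schedule(self) -> tuple[tuple[float, float, tuple[int, int]], ...]:
        if self.occupancy_schedule is None:
            return ((0.0, self.duration_s, self.chest_position),)
        return tuple(sorted(self.occupancy_schedule, key=lambda iv: iv[0]))


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side truth: schedule, rates, and the sensor layout used."""

    cfg: SimConfig
    layout: SensorLayout

    def _interval_at(self, t: float):
        for s, e, pos in self.cfg.schedule:
            if s <= t < e:
                return (s, e, pos)
        return None

    def table(self, period_s: float, hop_s: float) -> pd.DataFrame:
        """Per-window truth on the same grid the detector uses.

        A window is labelled occupied when its center falls inside an
        occupancy interval; turnover is flagged when the chest region differs
        from the previous occupied window's region.
        """
        n_windows = int((self.cfg.duration_s - period_s) // hop_s) + 1
        if self.cfg.duration_s < period_s:
            n_windows = 0
        rows = []
        prev_region = None
        for t in range(n_windows):
            start = t * hop_s
            center = start + period_s / 2.0
            iv = self._interval_at(center)
            occupied = iv is not None
            region = self.layout.region_of_cell(iv[2]) if occupied else None
            turnover = bool(
                occupied and prev_region is not None and region != prev_region
            )
            rows.append(
                {
                    "t_index": t,
                    "window_start_s": start,
                    "period_s": period_s,
                    "occupied": occupied,
                    "resp_per_min": self.cfg.resp_rate_per_min if occupied else np.nan,
                    "heart_per_min": self.cfg.heart_rate_per_min if occupied else np.nan,
                    "region": region,
                    "turnover": turnover,
                }
            )
            prev_region = region if occupied else None
        return pd.DataFrame(rows)


def _jittered_phase(rng: np.random.Generator, n: int, fs: float, rate_hz: float) -> np.ndarray:
    """Cycle phase (in cycles) with +-5% per-cycle period jitter."""
    duration = n / fs
    mean_period = 1.0 / rate_hz
    boundaries = [0.0]
    while boundaries[-1] < duration:
        boundaries.append(
            boundaries[-1]
            + mean_period * (1.0 + PERIOD_JITTER_FRAC * rng.uniform(-1, 1))
        )
    t = np.arange(n) / fs
    return np.interp(t, boundaries, np.arange(len(boundaries), dtype=float))


def _resp_waveform(rng: np.random.Generator, n: int, fs: float, cfg: SimConfig) -> np.ndarray:
    phase = _jittered_phase(rng, n, fs, cfg.resp_rate_per_min / 60.0)
    cycle_idx = np.floor(phase).astype(int)
    n_cycles = cycle_idx.max() + 1
    amps = 1.0 + AMP_JITTER_FRAC * rng.uniform(-1, 1, size=n_cycles)
    return cfg.resp_amplitude * amps[cycle_idx] * np.sin(2 * np.pi * phase)


def _heart_pulse_kernel(fs: float, width_s: float) -> np.ndarray:
    """Smooth biphasic pulse: difference of two offset bell curves.

    Each heartbeat deflects the mattress with an ejection lobe followed by a
    recoil lobe of opposite sign; the whole complex spans a few tenths of a
    second, so most of its energy sits near the heart fundamental rather than
    in a narrow spike.  Lobe scale is ``width_s`` (bell standard deviation)
    with lobe centers at -+1.5 x ``width_s``; the kernel is normalized to
    unit peak and has zero net area, so it does not bias the respiratory
    baseline.
    """
    sigma = width_s
    offset = 1.5 * width_s
    half = 4.0 * sigma + offset
    t = np.arange(-half, half, 1.0 / fs)
    pulse = np.exp(-((t + offset) ** 2) / (2 * sigma**2)) - np.exp(
        -((t - offset) ** 2) / (2 * sigma**2)
    )
    return pulse / np.abs(pulse).max()


def _heart_waveform(rng: np.random.Generator, n: int, fs: float, cfg: SimConfig) -> np.ndarray:
    """Unit-peak pulse train at the configured heart rate (+-2% beat jitter)."""
    out = np.zeros(n)
    kernel = _heart_pulse_kernel(fs, cfg.heart_pulse_width_s)
    k_center = int(np.argmax(kernel))
    mean_beat = 60.0 / cfg.heart_rate_per_min
    t_beat = mean_beat * rng.uniform(0.0, 1.0)  # random initial phase
    while t_beat < n / fs:
        start = int(round(t_beat * fs)) - k_center
        lo = max(0, start)
        hi = min(n, start + kernel.size)
        if hi > lo:
            out[lo:hi] += kernel[lo - start : hi - start]
        t_beat += mean_beat * (1.0 + 0.02 * rng.uniform(-1, 1))
    return out


def _channel_gains(layout: SensorLayout, chest: tuple[int, int], decay: float) -> np.ndarray:
    dist = np.linalg.norm(layout.positions - np.asarray(chest), axis=1)
    return decay**dist


def _movement_burst(rng: np.random.Generator, n: int, fs: float, duration_s: float, amp: float) -> np.ndarray:
    m = max(8, int(round(duration_s * fs)))
    noise = rng.normal(0.0, 1.0, size=m)
    b, a = butter(2, min(10.0, fs / 2 * 0.8), fs=fs, btype="low")
    burst = filtfilt(b, a, noise)
    burst *= tukey(m, alpha=0.5)
    peak = np.abs(burst).max()
    return amp * burst / peak if peak > 0 else burst


def simulate(cfg: SimConfig, layout: Optional[SensorLayout] = None) -> tuple[Recording, GroundTruth]:
    """Generate an 18-channel recording and its ground truth.

    Per channel i: offset + g_i * (resp + ratio * resp_amplitude * pulses)
    + mains + white noise (+ movement bursts), with g_i the geometric gain
    decay with grid distance from the chest cell; outside occupancy intervals
    only offset + mains + noise.  Identical config (including seed) gives
    bit-identical output.
    """
    layout = layout or SensorLayout.default()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    data = np.full((n, N_CHANNELS), cfg.baseline_offset)
    if cfg.mains_amplitude > 0:
        mains = cfg.mains_amplitude * np.sin(
            2 * np.pi * cfg.mains_freq * t + rng.uniform(0, 2 * np.pi)
        )
        data += mains[:, None]
    if cfg.white_noise_sd > 0:
        data += rng.normal(0.0, cfg.white_noise_sd, size=(n, N_CHANNELS))

    for s, e, chest in cfg.schedule:
        lo = int(round(s * cfg.fs))
        hi = min(n, int(round(e * cfg.fs)))
        if hi <= lo:
            continue
        seg = hi - lo
        resp = _resp_waveform(rng, seg, cfg.fs, cfg)
        heart = (
            cfg.heart_to_resp_ratio
            * cfg.resp_amplitude
            * _heart_waveform(rng, seg, cfg.fs, cfg)
        )
        gains = _channel_gains(layout, chest, cfg.gain_decay_per_cell)
        data[lo:hi] += np.outer(resp + heart, gains)

    for tm, dur, amp in cfg.movement_events:
        lo = int(round(tm * cfg.fs))
        if lo >= n:
            continue
        burst = _movement_burst(rng, n, cfg.fs, dur, amp)
        hi = min(n, lo + burst.size)
        iv = next((x for x in cfg.schedule if x[0] <= tm < x[1]), None)
        gains = (
            _channel_gains(layout, iv[2], cfg.gain_decay_per_cell)
            if iv is not None
            else np.ones(N_CHANNELS)
        )
        data[lo:hi] += np.outer(burst[: hi - lo], gains)

    rec = Recording(data=data, fs=cfg.fs, layout=layout)
    return rec, GroundTruth(cfg=cfg, layout=layout)


def score_against_truth(report: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Score a detector report against the simulator truth.

    Both frames must share the (window_start_s, period_s) grid.  Returns one
    row per method with mean respiratory/heart accuracy over windows where
    truth and detector agree the bed is occupied and the estimate is valid,
    plus occupancy confusion counts and true/detected turnover totals.
    """
    if report.empty:
        raise AlignmentError("detector report is empty")
    rows = []
    for method, grp in report.groupby("method"):
        merged = grp.merge(
            truth,
            on=["window_start_s", "period_s"],
            suffixes=("", "_true"),
            how="inner",
        )
        if len(merged) != len(truth) or len(merged) != len(grp):
            raise AlignmentError(
                f"report ({len(grp)} windows) and truth ({len(truth)}) are on different period grids"
            )
        both = merged[merged["occupied"] & merged["occupied_true"]]
        resp_acc = [
            accuracy(m, v)
            for m, v in zip(both["resp_per_min"], both["resp_per_min_true"])
            if np.isfinite(m)
        ]
        heart_acc = [
            accuracy(m, v)
            for m, v in zip(both["heart_per_min"], both["heart_per_min_true"])
            if np.isfinite(m)
        ]
        rows.append(
            {
                "method": method,
                "resp_accuracy_mean": float(np.mean(resp_acc)) if resp_acc else np.nan,
                "heart_accuracy_mean": float(np.mean(heart_acc)) if heart_acc else np.nan,
                "occupancy_tp": int((merged["occupied"] & merged["occupied_true"]).sum()),
                "occupancy_tn": int((~merged["occupied"] & ~merged["occupied_true"]).sum()),
                "occupancy_fp": int((merged["occupied"] & ~merged["occupied_true"]).sum()),
                "occupancy_fn": int((~merged["occupied"] & merged["occupied_true"]).sum()),
                "turnovers_true": int(merged["turnover_true"].sum()),
                "turnovers_detected": int(merged["turnover"].sum()),
            }
        )
    return pd.DataFrame(rows)
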