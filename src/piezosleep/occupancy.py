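"""Variance-based channel selection, bed-presence, and turnover detection.

Sensors near the chest see the largest pressure fluctuation, so the per-period
population variance S_{t,i} of each channel drives three decisions:

* channel selection - the maximum-variance channel carries the vitals;
* presence - the total variance over all 18 channels exceeds a calibrated
  threshold only when someone is on the mattress;
* turnover - the 6-channel region holding the maximum total variance changes
  when the sleeper turns over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError, LayoutError
from .signal_model import N_CHANNELS, PeriodWindow, SensorLayout


@dataclass(frozen=True)
class ChannelVariances:
    """Per-channel population variances for one time period."""

    t_index: int
    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        if s.shape != (N_CHANNELS,):
            raise LayoutError(f"expected {N_CHANNELS} variances, got shape {s.shape}")
        if np.any(s < 0):
            raise LayoutError("variances must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.s.sum())


@dataclass(frozen=True)
class PresenceDecision:
    cs: float
    threshold: float
    occupied: bool


@dataclass(frozen=True)
class RegionEnergy:
    """Total variance per region and the winning region for one period."""

    energies: dict[int, float]
    argmax_region: int


def channel_variance(w: PeriodWindow) -> float:
    """Population variance (divide by N) of one channel's period data."""
    return float(np.var(w.values))


def variances(window_set: Sequence[PeriodWindow]) -> ChannelVariances:
    """Collect S_{t,i} for all 18 channels of one period's window set."""
    if len(window_set) != N_CHANNELS:
        raise LayoutError(f"expected {N_CHANNELS} windows, got {len(window_set)}")
    return ChannelVariances(
        t_index=window_set[0].t_index,
        s=np.array([channel_variance(w) for w in window_set]),
    )


def select_channel(vars: ChannelVariances) -> int:
    """1-based id of the maximum-variance channel (ties -> lowest id)."""
    return int(np.argmax(vars.s)) + 1


def detect_presence(vars: ChannelVariances, threshold: float) -> PresenceDecision:
    """Occupied iff the total variance strictly exceeds the threshold."""
    if threshold < 0:
        raise LayoutError(f"threshold must be nonnegative, got {threshold}")
    cs = vars.total
    return PresenceDecision(cs=cs, threshold=threshold, occupied=cs > threshold)


def calibrate_threshold(empty_windows: Sequence[ChannelVariances], k: float = 5.0) -> float:
    """Presence threshold from empty-bed periods: mean(cs) + k*std(cs).

    Uses the population standard deviation over the empty-bed total
    variances; at least two periods are required.
    """
    if len(empty_windows) < 2:
        raise CalibrationError(
            f"need at least 2 empty-bed periods to calibrate, got {len(empty_windows)}"
        )
    cs = np.array([v.total for v in empty_windows])
    return float(cs.mean() + k * cs.std())


def region_energies(vars: ChannelVariances, layout: SensorLayout) -> RegionEnergy:
    """Total variance per region; winner is the max (ties -> lowest region id)."""
    energies: dict[int, float] = {}
    for rid in sorted(layout.region_ids.tolist()):
        members = layout.channels_in_region(rid)
        if members.size != 6:
            raise LayoutError(f"region {rid} has {members.size} channels, expected 6")
        energies[rid] = float(vars.s[members - 1].sum())
    best = max(energies, key=lambda rid: (energies[rid], -rid))
    return RegionEnergy(energies=energies, argmax_region=best)


def detect_turnover(prev: RegionEnergy, curr: RegionEnergy) -> bool:
    """True iff the maximum-variance region changed between occupied periods."""
    return prev.argmax_region != curr.argmax_region
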