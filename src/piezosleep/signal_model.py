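"""Core data types, recording I/O, and segmentation into analysis periods.

A recording is 18 synchronized pressure channels from a 2x9 sensor grid under
the mattress, sampled at a common rate (100 Hz in the reference hardware).
Detection algorithms consume fixed-duration *time periods* (typically 10, 30,
or 60 s) of a single channel, represented here by :class:`PeriodWindow`.

On-disk format: delimited text (CSV), one row per sample, columns
``ch01 .. ch18``, preceded by a ``# fs=<Hz>`` header line, plus an optional
JSON sidecar ``<name>.meta.json`` carrying ``fs``, the sensor layout, and the
start time.  Values are written with 9 significant digits, so a write/read
round trip preserves them to that precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, LayoutError, ParameterError

N_CHANNELS = 18
N_ROWS = 2
N_COLS = 9
CHANNELS_PER_REGION = 6


@dataclass(frozen=True)
class SampledSeries:
    """A uniformly sampled real-valued series (amplitudes in volts)."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.fs <= 0:
            raise ParameterError(f"sampling frequency must be positive, got {self.fs}")
        if values.ndim != 1 or values.size < 1:
            raise ParameterError("series must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ParameterError("series contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class SensorLayout:
    """Grid positions and region partition of the 18 sensor channels.

    ``positions[i]`` is the (row, col) cell of channel ``i+1`` on the 2x9
    grid; ``region_assignment[i]`` is the 1-based region id of channel
    ``i+1``.  Regions must partition the channels into groups of 6.
    """

    positions: np.ndarray
    region_assignment: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        reg = np.asarray(self.region_assignment, dtype=int)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "region_assignment", reg)
        if pos.shape != (N_CHANNELS, 2):
            raise LayoutError(f"expected {N_CHANNELS} (row, col) positions, got shape {pos.shape}")
        if reg.shape != (N_CHANNELS,):
            raise LayoutError("region assignment must list one region id per channel")
        ids, counts = np.unique(reg, return_counts=True)
        if not np.all(counts == CHANNELS_PER_REGION):
            raise LayoutError(
                f"regions must each contain {CHANNELS_PER_REGION} channels; got sizes {dict(zip(ids.tolist(), counts.tolist()))}"
            )

    @classmethod
    def default(cls) -> "SensorLayout":
        """2 rows x 9 columns; regions are column bands 1-3, 4-6, 7-9."""
        positions = np.array([((i // N_COLS), (i % N_COLS)) for i in range(N_CHANNELS)])
        regions = np.array([(i % N_COLS) // 3 + 1 for i in range(N_CHANNELS)])
        return cls(positions=positions, region_assignment=regions)

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.region_assignment)

    def channels_in_region(self, region_id: int) -> np.ndarray:
        """1-based channel ids belonging to ``region_id``."""
        return np.where(self.region_assignment == region_id)[0] + 1

    def region_of_cell(self, cell: tuple[int, int]) -> int:
        """Region id of the channel located at grid cell (row, col)."""
        hit = np.where((self.positions == np.asarray(cell)).all(axis=1))[0]
        if hit.size == 0:
            raise LayoutError(f"no channel at grid cell {cell}")
        return int(self.region_assignment[hit[0]])

    def channel_at_cell(self, cell: tuple[int, int]) -> int:
        hit = np.where((self.positions == np.asarray(cell)).all(axis=1))[0]
        if hit.size == 0:
            raise LayoutError(f"no channel at grid cell {cell}")
        return int(hit[0]) + 1

    def to_json_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "region_assignment": self.region_assignment.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SensorLayout":
        return cls(
            positions=np.asarray(d["positions"]),
            region_assignment=np.asarray(d["region_assignment"]),
        )


@dataclass(frozen=True)
class Recording:
    """18 equal-length channels sampled at a common rate.

    ``data`` has shape (n_samples, 18); column ``i`` is channel ``i+1``.
    """

    data: np.ndarray
    fs: float
    layout: SensorLayout = field(default_factory=SensorLayout.default)
    start_time: Optional[str] = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if self.fs <= 0:
            raise ParameterError(f"sampling frequency must be positive, got {self.fs}")
        if data.ndim != 2 or data.shape[1] != N_CHANNELS:
            found = data.shape[1] if data.ndim == 2 else data.ndim
            raise LayoutError(f"expected {N_CHANNELS} channels, found {found}")
        if data.shape[0] < 1:
            raise ParameterError("recording must contain at least one sample")
        if not np.all(np.isfinite(data)):
            raise ParameterError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: int) -> SampledSeries:
        """Return channel ``channel_id`` (1-based) as a SampledSeries."""
        if not 1 <= channel_id <= N_CHANNELS:
            raise ParameterError(f"channel id must be in 1..{N_CHANNELS}, got {channel_id}")
        return SampledSeries(self.data[:, channel_id - 1], self.fs)


@dataclass(frozen=True)
class PeriodWindow:
    """One channel's samples for one analysis time period."""

    data: SampledSeries
    period_s: float
    t_index: int
    channel: int

    def __post_init__(self) -> None:
        expected = self.period_s * self.data.fs
        if abs(expected - self.data.n) > 1e-9 or self.data.n < 1:
            raise ParameterError(
                f"window length {self.data.n} != period_s*fs = {expected}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def fs(self) -> float:
        return self.data.fs

    @property
    def n(self) -> int:
        return self.data.n


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV (+ JSON sidecar) re-readable by read_recording."""
    path = Path(path)
    header = "# fs=%.9g\n" % rec.fs + ",".join(f"ch{i:02d}" for i in range(1, N_CHANNELS + 1))
    try:
        np.savetxt(path, rec.data, fmt="%.9g", delimiter=",", header=header, comments="")
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc
    sidecar = {
        "fs": rec.fs,
        "layout": rec.layout.to_json_dict(),
        "start_time": rec.start_time,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, fmt: str = "csv") -> Recording:
    """Read a recording written by :func:`write_recording`.

    The sampling rate comes from the JSON sidecar if present, else from the
    ``# fs=`` header line; if neither exists a :class:`FormatError` is raised.
    """
    if fmt != "csv":
        raise FormatError(f"unknown recording format {fmt!r}")
    path = Path(path)
    fs = None
    layout = None
    start_time = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs")
        if meta.get("layout"):
            layout = SensorLayout.from_json_dict(meta["layout"])
        start_time = meta.get("start_time")

    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            body = first.lstrip("#").strip()
            if body.startswith("fs="):
                try:
                    header_fs = float(body[3:])
                except ValueError as exc:
                    raise FormatError(f"malformed fs header line {first!r}") from exc
                if fs is None:
                    fs = header_fs
            second = fh.readline()
            names = second.strip().split(",")
        else:
            names = first.split(",")
        if fs is None:
            raise FormatError(f"{path}: no sampling rate in sidecar or '# fs=' header")
        if len(names) != N_CHANNELS:
            raise LayoutError(f"expected {N_CHANNELS} channel columns, found {len(names)}")
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed data rows: {exc}") from exc
    if data.shape[1] != N_CHANNELS:
        raise LayoutError(f"expected {N_CHANNELS} channels, found {data.shape[1]}")
    return Recording(
        data=data, fs=fs, layout=layout or SensorLayout.default(), start_time=start_time
    )


def segment(rec: Recording, period_s: float, hop_s: float) -> list[list[PeriodWindow]]:
    """Slice the recording into per-period 18-channel window sets.

    Window ``t`` covers samples ``[t*hop_s*fs, t*hop_s*fs + period_s*fs)``;
    a trailing partial window is dropped.  A recording shorter than one
    period yields an empty list.
    """
    n_period = period_s * rec.fs
    if abs(n_period - round(n_period)) > 1e-9:
        raise ParameterError(f"period_s*fs = {n_period} is not an integer sample count")
    if hop_s > period_s:
        raise ParameterError("hop_s must not exceed period_s")
    if hop_s <= 0:
        raise ParameterError("hop_s must be positive")
    n_period = int(round(n_period))
    n_hop = int(round(hop_s * rec.fs))
    out: list[list[PeriodWindow]] = []
    t = 0
    while t * n_hop + n_period <= rec.n_samples:
        start = t * n_hop
        windows = [
            PeriodWindow(
                data=SampledSeries(rec.data[start : start + n_period, ch], rec.fs),
                period_s=period_s,
                t_index=t,
                channel=ch + 1,
            )
            for ch in range(N_CHANNELS)
        ]
        out.append(windows)
        t += 1
    return out
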