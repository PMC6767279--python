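"""Analytic operation-count and memory model of the three detectors.

Closed-form per-period costs for a data series of length N, counting
multiplications, additions, and comparisons separately (an embedded MCU pays
very differently for each), plus a storage estimate under 4-byte-float /
2-byte-integer accounting:

* wavelet analysis (4 basis wavelets, multilevel transform + peak search):
  (52 + 6 log2 N) N multiplications, 4 (1 + 3 log2 N) N additions, 4N
  comparisons; 42N floats + N ints of storage.
* EEMD with X sift iterations per IMF and Y IMFs: 3NXY multiplications,
  (4NX + N) Y additions, 4NXY + 4N comparisons; (2+Y)N floats + N ints.
* dynamic smoothing with half-windows W, w and alpha half-width L:
  3N + 1 multiplications, 2WN + 2wN + N + 4L additions, 4N comparisons;
  2N floats.

Non-integer values from the log2 terms are rounded to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

METHODS = ("wavelet", "eemd", "smoothing")


@dataclass(frozen=True)
class OpCount:
    multiplications: int
    additions: int
    comparisons: int

    def __post_init__(self) -> None:
        if min(self.multiplications, self.additions, self.comparisons) < 0:
            raise ParameterError("operation counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.multiplications + self.additions + self.comparisons


@dataclass(frozen=True)
class CostParams:
    """Problem sizes and per-datum byte costs of the cost model.

    Defaults: X = 100 sift iterations, Y = 9 IMFs, W = 83 and w = 20
    (the half-windows at the average sleep rates 0.3 Hz and 1.25 Hz with
    fs = 100 Hz), L = 10, four basis wavelets, 4-byte floats, 2-byte ints.
    """

    N: int
    X: int = 100
    Y: int = 9
    W: int = 83
    w: int = 20
    L: int = 10
    num_wavelets: int = 4
    float_bytes: int = 4
    int_bytes: int = 2

    def __post_init__(self) -> None:
        for name in ("N", "X", "Y", "W", "w", "L", "num_wavelets", "float_bytes", "int_bytes"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")


def wavelet_ops(p: CostParams) -> OpCount:
    """Operation counts of the four-wavelet multilevel analysis at length N."""
    log2n = math.log2(p.N)
    return OpCount(
        multiplications=round((52 + 6 * log2n) * p.N),
        additions=round(4 * (1 + 3 * log2n) * p.N),
        comparisons=4 * p.N,
    )


def eemd_ops(p: CostParams) -> OpCount:
    """Operation counts of EEMD with X sift iterations and Y IMFs."""
    return OpCount(
        multiplications=3 * p.N * p.X * p.Y,
        additions=(4 * p.N * p.X + p.N) * p.Y,
        comparisons=4 * p.N * p.X * p.Y + 4 * p.N,
    )


def smoothing_ops(p: CostParams) -> OpCount:
    """Operation counts of dynamic smoothing with half-windows W, w."""
    return OpCount(
        multiplications=3 * p.N + 1,
        additions=2 * p.W * p.N + 2 * p.w * p.N + p.N + 4 * p.L,
        comparisons=4 * p.N,
    )


def memory_bytes(method: str, p: CostParams) -> int:
    """Storage estimate in bytes for one method at length N."""
    if method == "wavelet":
        # 40 coefficient series + 2 reconstruction series in float,
        # plus the original integer samples.
        return 42 * p.N * p.float_bytes + p.N * p.int_bytes
    if method == "eemd":
        # 2 working series + Y stored IMFs in float, plus integer samples.
        return (2 + p.Y) * p.N * p.float_bytes + p.N * p.int_bytes
    if method == "smoothing":
        # only the series and its smoothed copy live at once.
        return 2 * p.N * p.float_bytes
    raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")


def op_table(p: CostParams) -> dict[str, OpCount]:
    """Operation counts for all three methods at the given parameters."""
    return {"wavelet": wavelet_ops(p), "eemd": eemd_ops(p), "smoothing": smoothing_ops(p)}


def memory_table(p: CostParams) -> dict[str, int]:
    """Memory estimates (bytes) for all three methods."""
    return {m: memory_bytes(m, p) for m in METHODS}
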