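"""Analytic per-period costs of the three detectors on an embedded target.

Evaluates the closed-form operation counts and storage estimates for one
10 s period (N = 1000 samples at 100 Hz) with the study defaults.  The
numbers explain why only dynamic smoothing fits a 32 KB microcontroller:
its memory footprint is 8 KB versus 170 KB (wavelet) and 46 KB (EEMD).
"""

from piezosleep import CostParams
from piezosleep.complexity import METHODS, memory_table, op_table

params = CostParams(N=1000)  # X=100, Y=9, W=83, w=20, L=10 defaults
ops = op_table(params)
mem = memory_table(params)

header = f"{'method':<10} {'mults':>10} {'adds':>10} {'cmps':>10} {'total':>10} {'bytes':>8}"
print(header)
print("-" * len(header))
for m in METHODS:
    o = ops[m]
    print(f"{m:<10} {o.multiplications:>10,} {o.additions:>10,} "
          f"{o.comparisons:>10,} {o.total:>10,} {mem[m]:>8,}")
# Dynamic smoothing needs ~46x fewer total operations than EEMD and is the
# only method whose working set (2 float series) fits alongside firmware.
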