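"""Trace loop-shaped power-efficiency curves for incomplete coupling.

An irreversible converter (q < 1) cannot reach every efficiency: its
power-vs-efficiency locus is a closed loop whose apex sits at the
maximal attainable efficiency eta_max(q).  At q = 1 the loop collapses
to the single-valued curve eta(1 - eta).
"""

import numpy as np

from litconv import eta_max, loop_area, loop_curve

for q in (1.0, 0.95, 0.8, 0.6):
    series = loop_curve("power", q, 201)
    i = np.argmax(series.value)
    print(
        f"q = {q:4.2f}: eta_max = {eta_max(q):.5f}  "
        f"peak power {series.value[i]:.5f} at eta = {series.eta[i]:.5f}  "
        f"loop area = {loop_area(series):.5f}"
    )

# The loop area (shoelace formula on the sampled polygon) is zero only
# for the degenerate q = 1 curve; it measures how far the converter's
# two operating branches separate as coupling weakens.
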