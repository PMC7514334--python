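"""Locate the three optimal operating regimes of the converter.

For a chosen degree of coupling q, each characteristic function —
power output, ecological function, efficient power — has a maximum at
some force ratio x*; mapping x* through the efficiency function gives
the regime's operating efficiency.  The closed forms are checked
against bounded numeric maximization (the residual column).
"""

from litconv import optimal_point

for q in (1.0, 0.95, 0.8):
    print(f"\ndegree of coupling q = {q}")
    for regime in ("MPO", "MEF", "MEPF"):
        r = optimal_point(regime, q)
        print(
            f"  {regime:4s}  eta* = {r.eta_star:.6f}  x* = {r.x_star:.6f}  "
            f"value* = {r.value_star:.6f}  |analytic-numeric| = {r.residual:.1e}"
        )

# At complete coupling (q = 1) the three efficiencies are the landmark
# rationals 1/2, 3/4 and 2/3.  At the mitochondrial coupling q = 0.95
# every optimum drops: maximum power is delivered at only 41% efficiency.
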