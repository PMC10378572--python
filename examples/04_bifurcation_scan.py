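"""Map entrainment and period structure over the (alpha, Delta) plane.

A coarse bifurcation scan at beta = 0.32: each cell integrates the
oscillator and reports the right-fold period count (number of distinct
Poincare crossing clusters).  '.' marks non-oscillatory cells (the rest
state is stable there), digits are period counts, and 'T' marks toroidal
cells (more than 12 clusters).  The single-cycle region at low Delta is the
normal-voice regime; tori appear at strong asymmetry.
"""

import numpy as np

from vfokit import bifurcation_scan

alpha_axis = np.linspace(0.30, 0.45, 6)
delta_axis = np.linspace(0.0, 0.9, 7)
grid = bifurcation_scan(alpha_axis, delta_axis, beta=0.32,
                        duration=1000.0, dt=0.05)

print("        alpha:", "  ".join(f"{a:.2f}" for a in alpha_axis))
for i in range(len(delta_axis) - 1, -1, -1):
    row = []
    for j in range(len(alpha_axis)):
        n = grid.period_count[i, j]
        if n == 0:
            row.append(".")
        elif grid.torus[i, j]:
            row.append("T")
        else:
            row.append(str(min(n, 9)))
    print(f"delta={delta_axis[i]:.2f}   " + "     ".join(row))
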