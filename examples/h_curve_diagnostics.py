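"""Locate the HATM convergence-control region from the h-curves.

The homotopy solution carries a free parameter h; the series converges for
h inside the flat region of the curves of the solution's initial
derivatives versus h.  This script tabulates those curves for the clinical
parameters and prints the detected plateau -- the interval from which a
safe h (conventionally its midpoint, h = -1) is chosen.
"""

import numpy as np

from fracliver import h_curve, initial_derivatives, plateau_region, table1_params

p = table1_params()
grid = np.arange(-2.0, -0.005, 0.01)
table = h_curve(p, grid)
plateau = plateau_region(table, slope_tol=0.05)

d = initial_derivatives(p, h=-1.0)
print(f"initial derivatives at h = -1:  R'(0) = {d.R1:.3f}, R''(0) = {d.R2:.4f}, "
      f"R'''(0) = {d.R3:.1f}")
print(f"                                W'(0) = {d.W1:.3f}, W''(0) = {d.W2:.4f}")
print(f"detected plateau: [{plateau.interval[0]:.2f}, {plateau.interval[1]:.2f}]")
print("Any h in this interval yields a convergent series; h = -1 (the")
print("midpoint of the conventional [-1.5, -0.5] choice) lies well inside.")
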