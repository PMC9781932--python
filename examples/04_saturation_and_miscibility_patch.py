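"""The iterative saturation solver and the miscibility repair.

First the ideal-solubility oracle: when the 'solvent' has the solute's
own sigma-profile, gamma = 1 and the solver must land on
x = exp(-dG_fus/RT) exactly.  Then a composition sweep where the solver
escapes to complete miscibility at organic-rich compositions, and the
flagged points are replaced by the linear ln x extrapolation through
the last five valid points.
"""

import numpy as np

import cosolv as cv
from cosolv.synth import amide_like_profile, water_like_profile

fusion = cv.FusionProps(**cv.FUSION_CONSTANTS["acetaminophen"])
solute = amide_like_profile()
T = 298.15

ideal = cv.solve_saturation(solute, [(solute, 1.0)], fusion, T)
closed = np.exp(-cv.fusion_gibbs(fusion, T) / (cv.R_GAS * T))
print(f"ideal-limit solubility: x = {ideal.x_sat:.6f} "
      f"(closed form {closed:.6f})")

# a synthetic sweep: linear co-solvency tail, then fake miscibility flags
grid = np.linspace(0.0, 1.0, 11)
ln_x = -6.0 + 4.5 * grid
flags = np.zeros(11, dtype=bool)
flags[-3:] = True              # solver reported x -> 1 at x2* >= 0.8
corrupted = ln_x.copy()
corrupted[-3:] = 0.0           # ln 1: complete-miscibility artefact

patched = cv.patch_miscibility(corrupted, flags, grid)
print(" x2*   raw ln x   patched")
for g, raw, fix in zip(grid, corrupted, patched):
    mark = " <- repaired" if raw != fix else ""
    print(f" {g:.1f}   {raw: 7.3f}   {fix: 7.3f}{mark}")
# The repaired tail continues the co-solvency trend instead of jumping
# to the nonphysical ln x = 0 plateau.
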