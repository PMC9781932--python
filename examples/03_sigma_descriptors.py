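"""sigma-potentials and the 8-descriptor vector for one solvent system.

An amide-like synthetic solute is placed in an 80:20 water/organic
mixture.  The sigma-potential mu(sigma) prices polar and apolar surface
in that environment; band averages give hydrogen-bond acceptance (HBA),
donation (HBD) and hydrophobicity (HYD) relative to the solvent, and
profile-averaged contact energies give the relative misfit / H-bond /
van der Waals shares (which sum to 1).
"""

import numpy as np

import cosolv as cv
from cosolv.synth import amide_like_profile, water_like_profile, \
    make_profile, ProfileSpec

solute = amide_like_profile()
water = water_like_profile()
organic = make_profile(ProfileSpec(
    peaks=((-0.012, 0.005, 1.0), (0.004, 0.006, 2.0)), total_area=120.0))

T = 298.15
components = [(organic, 0.2), (water, 0.8)]

fusion = cv.FusionProps(**cv.FUSION_CONSTANTS["acetaminophen"])
state = cv.solve_saturation(solute, components, fusion, T)
log10x = float(np.log10(state.x_sat))

vec = cv.descriptor_vector(solute, components, T, log10x)
print(f"saturation estimate: x = {state.x_sat:.4g} "
      f"(gamma = {state.gamma_sat:.2f}, {state.iterations} iterations)")
print("descriptor vector:")
for name, value in vec.as_dict().items():
    print(f"  {name:12s} = {value: .4f}")
shares = vec.as_dict()
closure = shares["dE_HB"] + shares["dE_vdW"] + shares["dE_misfit"]
print(f"energy-share closure: {closure:.12f}  (must be 1)")
# HBA/HBD/HYD are energies per contact relative to the solvent: negative
# HYD here flags a solute whose apolar surface is penalised by the
# largely aqueous environment.
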