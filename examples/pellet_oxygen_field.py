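"""Solve the steady oxygen field inside a single fungal pellet.

A 1400-um pellet (the smallest size class studied) with the measured
uptake kinetics and an effective diffusivity of 985 um^2/s, surface held
at 7 mg O2/l.  The two independent solvers are cross-checked and the key
observables printed.
"""

import numpy as np

from pelletox import MMKinetics, PelletGeometry, solve_pellet_profile

geom = PelletGeometry(1400.0)
kin = MMKinetics()  # r_max = 0.026 mg/l/s, K_M = 0.11 mg/l

shoot = solve_pellet_profile(geom, kin, d_eff=985.0, c_surface=7.0, method="shooting")
fd = solve_pellet_profile(geom, kin, d_eff=985.0, c_surface=7.0, method="finite_difference")

print(f"centre O2 concentration : {shoot.c_center:.3f} mg/l (surface 7.000)")
print(f"anoxic core radius      : {shoot.r_anox:.1f} um (0 = fully penetrated)")
print(f"observed uptake r_obs   : {shoot.r_obs * 1e3:.3f} ug/l/s "
      f"(volume average of the local rate)")
print(f"flux * a vs r_obs       : {shoot.flux_surface * geom.specific_area * 1e3:.3f} "
      f"ug/l/s (conservation check)")
print(f"solver cross-check      : max|dc| = "
      f"{np.max(np.abs(shoot.c - fd.c)):.2e} mg/l between shooting and FD")
# The centre still sees ~4.9 mg/l: a 1400-um pellet at this diffusivity
# is almost fully oxygen-penetrated, consistent with its near-kinetic
# regime classification.
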