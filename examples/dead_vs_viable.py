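"""Contrast oxygen profiles of respiring and deactivated pellets.

A viable pellet at steady state is compared with a deactivated
(non-respiring) pellet of the same geometry after 10 minutes of pure
inward diffusion from an oxygen-free start — the experimental contrast
used to demonstrate that uptake, not just diffusion resistance, shapes
the measured profiles.
"""

import numpy as np

from pelletox import ProfileScenario, generate_dead_profile, generate_profile

scenario = ProfileScenario(noise_sd=0.0)  # noiseless model curves
viable, v_truth = generate_profile(scenario)
dead, d_truth = generate_dead_profile(scenario, elapsed_time_s=600.0)

surface = scenario.surface_depth
print(f"{'depth (um)':>10} {'r (um)':>7} {'viable':>8} {'dead':>8}  (mg O2/l)")
for depth in np.arange(surface, surface + 1001.0, 200.0):
    i = np.argmin(np.abs(v_truth.positions - depth))
    r = scenario.geometry.radius - (v_truth.positions[i] - surface)
    print(f"{v_truth.positions[i]:10.0f} {r:7.0f} "
          f"{v_truth.concentrations[i]:8.3f} {d_truth.concentrations[i]:8.3f}")

margin = np.min(d_truth.concentrations - v_truth.concentrations)
print(f"\nmin (dead - viable) over all depths: {margin:.3f} mg/l (>= 0)")
# The dead pellet is everywhere at least as oxygenated as the viable
# one; its remaining centre deficit after 10 min shows pure diffusion
# has not yet reached steady state (Fourier number ~ 0.5).
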