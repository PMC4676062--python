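"""The sine-Gordon pendulum chain: mechanical analog of protein ILMs.

A kink on a 17-pendulum chain is an exactly localized excitation; its
unit-vector displacement profile feeds the same entropy statistic as
the protein pipeline and lands below the S = 0.5 ILM cutoff.
"""

import numpy as np

from ilmscan import (
    SGChainState,
    breather_initialize,
    kink_profile,
    profile_entropy,
    sg_displacement_profile,
    step,
    topological_charge,
    total_energy,
)

n, center = 17, 10.0
kink = SGChainState(alpha=kink_profile(n, center, width=1.0), alpha_dot=np.zeros(n))
du2 = sg_displacement_profile(np.zeros(n), kink)
print(f"kink on {n} pendulums, centered at {center:.0f}:")
print(f"  du2 peak at pendulum {np.argmax(du2) + 1}, value {du2.max():.2f}")
print(f"  localization entropy S = {profile_entropy(du2):.3f} (ILM cutoff 0.5)")
print(f"  topological charge = {topological_charge(kink):.3f}")

E0 = total_energy(kink)
evolved = step(kink, dt=1e-3, n_steps=100_000)
drift = abs(total_energy(evolved) - E0) / E0
print(f"  energy drift over 1e5 velocity-Verlet steps: {drift:.2e} (relative)")

b = breather_initialize(n, center - 1, width=1.0, separation=2.0, velocity=0.2)
print(f"breather (kink-antikink superposition): charge = {topological_charge(b):.3f}")
for _ in range(3):
    b = step(b, dt=5e-3, n_steps=400)
    du2 = sg_displacement_profile(np.zeros(n), b)
    print(f"  t = {b.time:4.1f}: du2 peak at pendulum {np.argmax(du2) + 1}, "
          f"S = {profile_entropy(du2):.3f}")
# The breather oscillates in time but its localization stays pinned
# near the chosen center -- localized in space, periodic in time.
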