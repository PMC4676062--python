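"""Free-energy basins, native character NC(t), and per-state soliton rates.

A reference trajectory defines each site's native basin (bins within
3 kT of the free-energy minimum).  An analysis trajectory spends its
first half in those basins and its second half shifted out of them with
a 10x higher localized-event rate; the per-state rate table recovers
the contrast.
"""

import numpy as np

from ilmscan import (
    Segment,
    SyntheticSpec,
    detect_ilms,
    displacements,
    draw_poisson_events,
    free_energy_map,
    generate_angles,
    native_basins,
    native_character,
    shares_and_entropy,
    state_rates,
    unit_vectors,
)

# native-state reference: build one 3-kT basin mask per CGA site
ref = generate_angles(SyntheticSpec(n_residues=20, n_frames=50_000,
                                    gamma_std=8.0, theta_std=4.0, seed=1))
masks = {int(s): native_basins(free_energy_map(ref, int(s)), cutoff_kT=3.0)
         for s in ref.site_index}

# analysis: 50 ns native, then 50 ns shifted out of the basins, events 10x
spec = SyntheticSpec(
    n_residues=20, n_frames=100_000, gamma_std=8.0, theta_std=4.0, seed=2,
    segments=[Segment(0, 50_000, rate_multiplier=1.0),
              Segment(50_000, 100_000, gamma_shift_deg=120.0, rate_multiplier=10.0)],
)
spec.events = draw_poisson_events(spec, rate_per_ns=0.6, rng=3)
angles = generate_angles(spec)

nc = native_character(angles, masks)  # smoothed over 1 ns, threshold 80%
print(f"NC mean, first half:  {nc.NC[:50_000].mean():5.1f} %")
print(f"NC mean, second half: {nc.NC[50_000:].mean():5.1f} %")

d = displacements(unit_vectors(angles))
events = detect_ilms(shares_and_entropy(d), d, cutoff=0.5)
table = state_rates(nc, events)
p = table.printed()
print(f"native:     t_n  = {p['t_n']:6.1f} ns   N_n  = {p['N_n']:3d}   "
      f"P_n  = {p['P_n']:.3f} /ns")
print(f"non-native: t_nn = {p['t_nn']:6.1f} ns   N_nn = {p['N_nn']:3d}   "
      f"P_nn = {p['P_nn']:.3f} /ns")
print(f"rate ratio P_nn/P_n = {p['ratio']:.1f} (true contrast: 10)")
# Counting noise on the native-segment events dominates the deviation
# from the true 10x contrast.
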