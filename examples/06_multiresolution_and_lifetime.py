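"""Multi-resolution entropy statistics and the lifetime of one soliton.

A fine-stride analysis (1-ps displacement window shifted every fs, i.e.
window = 1000 fine frames, stride = 1) resolves the sub-picosecond life
of a localized event; P(S) itself barely depends on the window used.
"""

import numpy as np

from ilmscan import (
    KinkEvent,
    SyntheticSpec,
    cumulative_displacement,
    detect_ilms,
    displacements,
    entropy_distribution,
    event_lifetime,
    generate_angles,
    shares_and_entropy,
    unit_vectors,
)

# femtosecond-resolution trajectory (frame_spacing 0.001 ps) with one
# 400-fs kink ramp at site 10
spec = SyntheticSpec(
    n_residues=20, n_frames=20_000, frame_spacing=0.001, gamma_std=6.0,
    theta_std=3.0, autocorr_time=1.0, seed=8,
    events=[KinkEvent(site=10, start=10_000, duration=400,
                      excursion_deg=140.0, shape="step")],
)
angles = generate_angles(spec)
u = unit_vectors(angles)

for window in (1000, 100, 10):  # 1 ps, 100 fs, 10 fs windows, shifted every fs
    d = displacements(u, window=window, stride=1)
    trace = shares_and_entropy(d)
    density, edges = entropy_distribution(trace, n_bins=20)
    tail = np.nanmean(trace.S <= 0.5)
    print(f"window {window * spec.frame_spacing * 1000:5.0f} fs: "
          f"mean S = {np.nanmean(trace.S):.3f}, P(S <= 0.5) = {tail:.4f}")

d = displacements(u, window=1000, stride=1)
trace = shares_and_entropy(d)
events = detect_ilms(trace, d, cutoff=0.5)
ev = min(events, key=lambda e: e.S_value)
life_ps = event_lifetime(trace, ev, cutoff=0.5)
print(f"soliton at site {ev.site}: S_min = {ev.S_value:.3f}, "
      f"lifetime = {life_ps * 1000:.0f} fs "
      "(injected ramp 400 fs, smeared by the 1000-fs window)")

c = cumulative_displacement(u, ev.site, ev.frame - 5000, min(ev.frame + 5000, u.n_frames - 1))
print(f"cumulative du2 at the event site over +/-5 ps: 0 -> {c[-1]:.2f}")
# The entropy dip tracks the injected ramp duration; the cumulative
# displacement shows the site settling into its new orientation.
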