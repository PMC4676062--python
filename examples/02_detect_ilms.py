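"""Detect intrinsic localized modes with the normalized Shannon entropy.

Injects three large single-site gamma rotations into an otherwise
harmonic-like baseline and shows that exactly those frames drop below
the S <= 0.5 localization cutoff.
"""

import numpy as np

from ilmscan import (
    KinkEvent,
    SyntheticSpec,
    detect_ilms,
    displacements,
    generate_angles,
    label_transition,
    shares_and_entropy,
    unit_vectors,
)

spec = SyntheticSpec(
    n_residues=20, n_frames=5000, gamma_std=8.0, theta_std=4.0, seed=4,
    events=[
        KinkEvent(site=10, start=1000, excursion_deg=150.0, shape="step"),
        KinkEvent(site=9, start=2500, excursion_deg=120.0, shape="pulse"),
        KinkEvent(site=14, start=4000, excursion_deg=130.0, shape="pulse"),
    ],
)
angles = generate_angles(spec)
d = displacements(unit_vectors(angles))          # 1-frame window: consecutive snapshots
trace = shares_and_entropy(d)
print(f"baseline entropy: mean S = {np.nanmean(trace.S):.3f} "
      f"(S = 1 is fully delocalized)")

events = detect_ilms(trace, d, cutoff=0.5)
print(f"{len(events)} ILM events at S <= 0.5:")
for ev in events:
    ev.transition = label_transition(angles, ev)
    print(f"  t = {ev.time:6.0f} ps  site {ev.site:2d}  S = {ev.S_value:.3f}  "
          f"du2 = {ev.amplitude:.2f}  {ev.event_class}  {ev.transition}")
# Each detection sits at the injected site; amplitudes are the squared
# chord of the unit-vector jump (2 = 90-degree rotation, 4 = antipodal).
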