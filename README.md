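# ilmscan

Detection and statistics of **intrinsic localized modes (ILMs)** — rare,
soliton-like excitations of the protein main chain — in Cα-resolved
molecular-dynamics trajectories.

Proteins are discrete, strongly anharmonic lattices, and such lattices
generically support excitations that concentrate on one site instead of
spreading as ordinary phonons. `ilmscan` implements the full
post-processing pipeline that finds these events in MD data and is
aimed at people who run or analyze protein simulations: it reduces a
trajectory to coarse-grained backbone angles, scores the localization
of every frame's main-chain fluctuation with a normalized Shannon
entropy, relates events to the free-energy landscape and the protein's
native/non-native state, and ships the discrete sine-Gordon pendulum
chain whose kinks and breathers are the mechanical analog of the
protein events. A seeded synthetic-trajectory generator makes the whole
pipeline testable without production MD runs.

## The statistic

For an N-residue chain, each residue window i = 2..N−2 carries a
coarse-grained angle pair: the pseudo-dihedral γ_i of four consecutive
Cα atoms and the pseudo-bond angle θ_i of three. Each pair maps to a
unit vector

    u_i = (cos γ_i sin θ_i, sin γ_i sin θ_i, cos θ_i),

and the fluctuation between two snapshots is Δu_i(t) = u_i(t) − u_i(t−1).
The per-site shares p_i(t) = Δu_i² / Σ_j Δu_j² define the normalized
Shannon entropy

    S(t) = − Σ_i p_i ln p_i / ln(N−3),   0 ≤ S ≤ 1,

with S = 0 for a fluctuation carried by a single site and S = 1 for a
perfectly uniform one. ILMs are the rare frames with S ≤ 0.5; the
cutoff can be re-calibrated by requiring that all event amplitude
profiles localized at the same site stay Pearson-correlated above 0.9.
Effective free energies are Boltzmann inversions V(γ,θ) = −kT ln P of
the per-site angle histograms; a site's *native basin* is the region
within 3 k_BT of the minimum of the map built from a reference
(native-state) trajectory, the *native character* NC(t) is the
percentage of sites currently inside their basins, and soliton-type
events (those away from the chain termini) are rated per native /
non-native state in events per ns.

## Worked example

`examples/02_detect_ilms.py` injects three large localized γ rotations
into a harmonic-like baseline (20 residues, 5000 frames, γ std 8°) and
runs the detector:

```text
baseline entropy: mean S = 0.834 (S = 1 is fully delocalized)
3 ILM events at S <= 0.5:
  t =   1001 ps  site 10  S = 0.185  du2 = 3.89  soliton  cis_to_trans
  t =   2501 ps  site  9  S = 0.235  du2 = 2.97  soliton  none
  t =   4001 ps  site 14  S = 0.210  du2 = 3.38  soliton  none
```

The thermal baseline sits near S ≈ 0.83; each injected event — and
nothing else — drops below the 0.5 cutoff, at the injected site and
time. The amplitude is the squared chord of the unit-vector jump
(2 ⇒ a 90° rotation, 4 ⇒ antipodal), and the first event's sustained
150° rotation is labeled as a cis→trans transition of its four-Cα
segment. The other examples cover chain reconstruction, cutoff
calibration, native-state rate ratios, the sine-Gordon analog, and
multi-resolution entropy statistics with event lifetimes.

There is also a thin CLI:

```bash
ilmscan synth --n-residues 20 --n-frames 2000 --n-events 3 --out traj.pdb
ilmscan detect --topology traj.pdb --out-dir out/
ilmscan sg --mode kink --n 17 --center 10
```

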