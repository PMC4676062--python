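# Methods

## Coarse-grained angle geometry

The main chain is reduced to its Cα trace with a fixed virtual bond
length (3.8 Å). For residues i = 2..N−2 the pair (γ_i, θ_i) — the
dihedral of Cα(i−1..i+2) and the bond angle of Cα(i−1..i+1) — fully
determines the chain shape up to a rigid-body motion, so an N-residue
chain carries exactly N−3 angle sites per frame. Angles are degrees at
every API boundary (γ ∈ (−180, 180], cis = 0; θ ∈ [0, 180]) and
radians internally.

The dihedral is the standard atan2 form. The overall handedness is
fixed once by the package-wide constant `DIHEDRAL_SIGN = +1`; the
mirror-antisymmetry property (reflecting the coordinates negates every
γ and preserves every θ) pins the convention in the test suite, and the
magnitude is cross-checked against MDAnalysis. Degenerate geometry
(coincident atoms, collinear virtual bonds) raises
`DegenerateGeometryError` with frame and site indices rather than
returning NaN — silent NaNs would corrupt the entropy statistics
downstream, and the synthetic generator *can* produce exact
collinearity.

Displacements are squared chords of the spherical unit vectors on a
sliding window: `window` fine frames per displacement, `stride` frames
between successive windows. The displacement spanning [t, t+window] is
attributed to the *later* frame t+window, so event timestamps mark the
moment an excitation is detected. The default window = stride = 1 frame
is the consecutive-snapshot analysis; window ≫ stride (e.g. a 1000-frame
window shifted every frame on femtosecond-spaced data) is the
multi-resolution variant.

## Localization entropy and event detection

Shares p_i = Δu_i²/ΣΔu_j² and S = −Σ p_i ln p_i / ln(N−3), with
0·ln 0 = 0. Frames with exactly zero total displacement have undefined
shares; their S is NaN and they are excluded from every statistic —
never coerced to 0 or 1, since either choice would bias the tails where
ILMs live.

Detection keeps frames with S ≤ cutoff (default 0.5) and assigns each
to the site of max p_i. Consecutive qualifying frames at the same site
within one window length merge into a single event that keeps the
minimal-S frame: on fine-stride analyses one physical excitation would
otherwise be counted hundreds of times. Both the merged-event count and
the per-event `n_merged` (qualifying-frame count) are reported, since a
frame-based and an event-based census differ exactly by that factor.

Events at the first or last CGA site (i = 2 or N−2) are classed
`terminal`: such end-of-chain localization exists even in a purely
harmonic free-ended chain (broken translational symmetry) and is not
soliton-like, so terminal events are excluded from state-rate
statistics. cis/trans labels compare circular-mean γ (vector averaging,
never arithmetic means of raw degrees — wrap-around at ±180° would
corrupt them) over windows before and after the event: |γ| < 60° is
cis, |γ| > 120° is trans, and anything landing in the neutral band in
either window is `none`, which keeps incomplete rotations
representable. Both band edges are configurable; the defaults are
symmetric bands with a 60° gap.

Cutoff calibration sweeps the candidate grid 0.40–0.60 in steps of
0.05 (bracketing every cutoff worth discussing for this statistic).
For each candidate, events are grouped by site; at each site with ≥ 2
events the Pearson correlation of every event's Δu_i² profile against
the maximal-amplitude event at that site must exceed ρ_min = 0.9. The
reference-based reduction is deterministic and O(n); an all-pairs mode
is available (`mode="pairwise"`). The largest passing candidate wins; a
trajectory with no repeated site at any candidate is inconclusive and
falls back to 0.5 with a flag.

## Free-energy landscapes and native states

V(γ,θ) = −ln(P/P_max) in k_BT units on a per-site 2-D histogram:
72 γ-bins × 36 θ-bins (5° cells), with γ periodic. The bin widths keep
typical long-trajectory occupancy high in the wells while resolving
basin shapes; they are configurable. Empty bins carry +∞ — pseudo-counts
would silently enlarge basins — and the occupied minimum is the zero of
energy. 1-D profiles V(γ), V(θ) use the same construction on marginals.

A native basin is the full sub-level set {V ≤ 3 k_BT} of the
reference-trajectory map, whether or not contiguous with the global
minimum (isolines in angle space are level sets; a connected-component
mode with γ-periodic stitching is available). NC(t) is the percentage
of sites inside their basins, smoothed by a centered moving average
(default 1 ns of frames; the window shrinks at the trace edges).
State labels are computed on the *smoothed* trace: native while
smoothed NC ≥ 80%, flipping only below 75% (5% hysteresis prevents
label chattering at the boundary). Threshold and hysteresis are
configurable; nothing in the rate machinery depends on the particular
values beyond the segmentation they induce.

Rates are events per ns: soliton-class events are assigned to the state
label at their detection frame, divided by the state's total duration.
`StateRateTable.ratio` is the exact P_nn/P_n (with an explicit
infinite-ratio flag when the native count is zero);
`StateRateTable.printed()` additionally reproduces the publication
convention in which the ratio column is formed from the 3-decimal
rounded rates.

## Sine-Gordon pendulum chain

The mechanical analog is α̈_i = C(α_{i+1} − 2α_i + α_{i−1}) − ω₀² sin α_i
with free ends, in natural units (unit inertia and lattice spacing;
C = ω₀² = 1 by default, chain length 17 to mirror a 20-residue
protein's site count). The integrator is velocity-Verlet — symplectic
and second order, chosen because long-run energy behavior is itself an
acceptance property (drift < 10⁻⁶ relative over 10⁵ steps at dt = 10⁻³
is verified; dt must stay well below both 1/ω₀ and 1/√C, and divergence
raises with that advice). Kinks are α_i = 4 arctan exp((i−c)/w); the
breather initializer superposes a kink and an antikink with opposite
velocities — an illustrative localized oscillation, not an exact
discrete-breather solution (no numerical continuation is attempted).
Planar unit vectors (cos α, sin α) feed the same entropy statistic as
the protein pipeline; a width-1 kink on 17 sites scores S ≈ 0.46,
below the ILM cutoff, which is the quantitative bridge between the
analog and the detector.

## Synthetic trajectories

The generator emulates exactly the statistical structure the detector
assumes, and nothing more:

- **Baseline**: per-site stationary AR(1) (discrete Ornstein–Uhlenbeck)
  noise on γ and θ with configurable std (defaults 8° and 4° — small
  harmonic-like thermal fluctuation) and autocorrelation time (default
  1 ps, so multi-window analyses see nontrivial time structure; white
  noise would make them degenerate). The stationary std is matched
  exactly, including the initial condition.
- **Events**: smooth localized γ excursions at a site, either `step`
  (cosine ramp to a sustained offset — the cis→trans rotation picture;
  default duration 1 frame at ps spacing, 400 frames at fs spacing) or
  `pulse` (rises and returns within the duration). Pulses are used in
  long-run rate experiments so repeated events do not cumulatively walk
  a site out of its native basin.
- **Segments**: frame ranges with shifted per-site means (moving sites
  out of reference basins) and event-rate multipliers;
  `draw_poisson_events` samples event times accordingly.
- **Chain reconstruction**: sequential internal-coordinate (NeRF)
  placement with the canonical frame atom1 = origin, atom2 on +x,
  atom3 in the xy-plane (y > 0). The site list 2..N−2 carries one fewer
  bond angle than a full chain needs (θ at residue N−1), which is
  padded with θ_{N−2}; the padding only positions the last atom in a
  way no recoverable site angle depends on, so the round trip is exact
  to numerical precision (< 10⁻⁶ degrees, tested over seeded draws).

A seed fully determines the output (bit-identical arrays).

What the generator does **not** model: real backbone stereochemistry or
excluded volume, solvent, any force-field realism, correlated
multi-site motions, or a protein-specific free-energy surface. Passing
tests therefore demonstrate that the *pipeline* is correct — that
localized events of known amplitude, site and rate are recovered with
the stated sensitivity and false-positive behavior — not that any
particular protein exhibits them.

## Problem sizes and numerical choices

The test suite and examples run trajectories of 10⁴–10⁵ frames with
N = 20 (17 sites): large enough that baseline entropy statistics,
Poisson event counts and histogram free energies are in their
well-sampled regimes, while the whole suite stays interactive.
Injection-recovery uses 50 events of Δu² = 3 (120° γ rotation at
θ ≈ 90°) against an 8° baseline, recovering ≥ 95% at the correct site
with < 10⁻³ false-positive frames; free-energy recovery rebuilds a
known harmonic 2-D potential from 10⁵ Boltzmann samples to < 0.15 k_BT
RMS below the 3 k_BT isoline; the two-state experiment measures a 10×
rate contrast within three counting-noise standard errors.

Other degenerate-input rules: entropy needs ≥ 2 sites; free-energy maps
warn below 1000 frames; event lifetimes are defined only for events
whose frame is actually below the cutoff; angle tables must cover all
sites a basin analysis needs (missing masks raise).

## Known limitations

- The cis/trans bands, NC threshold/hysteresis and histogram bins are
  reasonable defaults, not fitted quantities; analyses near their
  boundaries should report sensitivity.
- Event merging is purely temporal (one window length at one site); two
  genuinely distinct excitations of the same site inside one window
  merge.
- The breather is a kink–antikink superposition; its period and
  stability are approximate.
- PDB/XTC round trips are limited by format precision (~0.05°/~0.4° in
  the angles on short chains); use DCD or the HDF5 angle store when
  exact reproducibility matters.
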