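"""Synthetic (γ, θ) trajectories with injected localized excitations.

The generator emulates the statistical structure the detector assumes in
real MD data:

* a per-site baseline of small, mean-reverting angular fluctuations
  (discrete Ornstein–Uhlenbeck / AR(1) process with a configurable
  standard deviation and autocorrelation time — white noise would make
  the multi-resolution window analysis trivial);
* rare injected *kink events*: smooth, large, localized γ excursions of
  prescribed amplitude and duration, either sustained ("step", the
  cis→trans rotation picture) or returning to baseline ("pulse");
* optional segments that shift the per-site mean angles (out of a
  reference native basin) and scale the event rate, giving a two-state
  native/non-native scenario;
* reconstruction of consistent Cα coordinates from the angles by
  sequential internal-coordinate (NeRF) chain building, so the geometry
  readers and writers are exercised end to end.

A seed fully determines the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AngleTrajectory, CalphaTrajectory

__all__ = [
    "KinkEvent",
    "Segment",
    "SyntheticSpec",
    "generate_angles",
    "draw_poisson_events",
    "chain_from_angles",
    "write_trajectory",
]

CA_CA_BOND_LENGTH = 3.8  # Å, nearly constant in real chains


@dataclass(frozen=True)
class KinkEvent:
    """One injected localized γ excursion.

    ``shape='step'`` ramps γ smoothly by ``excursion_deg`` over
    ``duration`` frames and stays (a sustained rotation);
    ``shape='pulse'`` rises and returns to baseline within ``duration``
    frames.
    """

    site: int
    start: int
    duration: int = 1
    excursion_deg: float = 120.0
    shape: str = "step"  # step | pulse


@dataclass(frozen=True)
class Segment:
    """A trajectory portion with optionally shifted means and scaled event rate."""

    start: int
    end: int  # exclusive
    gamma_shift_deg: float = 0.0
    theta_shift_deg: float = 0.0
    rate_multiplier: float = 1.0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic angle trajectory.

    Baseline means/stds are scalars or per-site arrays (degrees);
    ``autocorr_time`` is the OU correlation time in ps.  The seed fully
    determines the output.
    """

    n_residues: int = 20
    n_frames: int = 10_000
    frame_spacing: float = 1.0  # ps
    gamma_mean: float | np.ndarray = 60.0
    theta_mean: float | np.ndarray = 90.0
    gamma_std: float | np.ndarray = 8.0
    theta_std: float | np.ndarray = 4.0
    autocorr_time: float = 1.0  # ps
    events: list[KinkEvent] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return self.n_residues - 3

    @property
    def site_index(self) -> np.ndarray:
        return np.arange(2, self.n_residues - 1)


def _per_site(value, n_sites: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_sites,)).copy()
    return arr


def _ar1(
    rng: np.random.Generator,
    n_frames: int,
    n_sites: int,
    std: np.ndarray,
    a: float,
) -> np.ndarray:
    """Stationary AR(1) noise: x_t = a x_{t−1} + std√(1−a²) ξ_t."""
    from scipy.signal import lfilter

    if np.all(std == 0):
        return np.zeros((n_frames, n_sites))
    white = rng.standard_normal((n_frames, n_sites))
    x = lfilter([1.0], [1.0, -a], white, axis=0)
    # draw the initial condition from the stationary distribution
    x0 = rng.standard_normal(n_sites) / np.sqrt(1.0 - a**2)
    x += x0 * a ** np.arange(1, n_frames + 1)[:, None]
    return x * std * np.sqrt(1.0 - a**2)


def _event_offsets(spec: SyntheticSpec) -> np.ndarray:
    off = np.zeros((spec.n_frames, spec.n_sites))
    site_cols = {int(s): c for c, s in enumerate(spec.site_index)}
    for ev in spec.events:
        if ev.site not in site_cols:
            raise ValueError(
                f"event site {ev.site} outside valid sites 2..{spec.n_residues - 2}"
            )
        if ev.duration < 1:
            raise ValueError("event duration must be >= 1 frame")
        if ev.start < 1 or ev.start + ev.duration >= spec.n_frames:
            raise ValueError(
                f"event at frame {ev.start} (duration {ev.duration}) overlaps the trajectory ends"
            )
        col = site_cols[ev.site]
        if ev.shape == "step":
            # smooth cosine ramp 0 -> A over `duration` frames, sustained after
            t = np.arange(ev.start, spec.n_frames)
            ramp = np.minimum((t - ev.start) / ev.duration, 1.0)
            off[t, col] += ev.excursion_deg * 0.5 * (1.0 - np.cos(np.pi * ramp))
        elif ev.shape == "pulse":
            # rise and return within `duration` frames
            t = np.arange(ev.start, ev.start + ev.duration)
            phase = (t - ev.start + 1) / (ev.duration + 1)
            off[t, col] += ev.excursion_deg * np.sin(np.pi * phase) ** 2
        else:
            raise ValueError(f"unknown event shape {ev.shape!r}")
    return off


def generate_angles(spec: SyntheticSpec) -> AngleTrajectory:
    """Generate the (γ, θ) trajectory described by ``spec``.

    γ is wrapped to (−180, 180]; θ is clipped away from the degenerate
    poles (0.5° margin) so chain reconstruction stays well posed.
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.n_sites
    if M < 1:
        raise ValueError("need n_residues >= 4")
    a = float(np.exp(-spec.frame_spacing / spec.autocorr_time))
    g_std = _per_site(spec.gamma_std, M)
    t_std = _per_site(spec.theta_std, M)
    gamma = _per_site(spec.gamma_mean, M) + _ar1(rng, spec.n_frames, M, g_std, a)
    theta = _per_site(spec.theta_mean, M) + _ar1(rng, spec.n_frames, M, t_std, a)
    for seg in spec.segments:
        if not (0 <= seg.start < seg.end <= spec.n_frames):
            raise ValueError(f"segment [{seg.start}, {seg.end}) out of range")
        gamma[seg.start : seg.end] += seg.gamma_shift_deg
        theta[seg.start : seg.end] += seg.theta_shift_deg
    gamma += _event_offsets(spec)
    gamma = (gamma + 180.0) % 360.0 - 180.0
    gamma[gamma == -180.0] = 180.0
    theta = np.clip(theta, 0.5, 179.5)
    return AngleTrajectory(
        gamma=gamma,
        theta=theta,
        site_index=spec.site_index,
        frame_spacing=spec.frame_spacing,
    )


def draw_poisson_events(
    spec: SyntheticSpec,
    rate_per_ns: float,
    rng: np.random.Generator | int | None = None,
    excursion_deg: float = 120.0,
    duration: int = 1,
    shape: str = "pulse",
    sites: np.ndarray | None = None,
    min_separation: int = 10,
) -> list[KinkEvent]:
    """Draw kink events as a Poisson process, honoring segment rate multipliers.

    The base rate is in events per ns; each segment of ``spec`` scales
    it by its ``rate_multiplier`` (frames outside any segment use the
    base rate).  Events are placed at uniformly drawn interior sites
    (or ``sites``), at least ``min_separation`` frames apart so injected
    events remain individually resolvable.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    rate_per_frame = np.full(spec.n_frames, rate_per_ns * spec.frame_spacing * 1e-3)
    for seg in spec.segments:
        rate_per_frame[seg.start : seg.end] *= seg.rate_multiplier
    margin = duration + 1
    rate_per_frame[:margin] = 0.0
    rate_per_frame[-(margin + 1) :] = 0.0
    hits = np.nonzero(rng.random(spec.n_frames) < rate_per_frame)[0]
    if sites is None:
        sites = spec.site_index[1:-1] if spec.n_sites > 2 else spec.site_index
    events: list[KinkEvent] = []
    last = -(10**9)
    for t in hits:
        if t - last < min_separation:
            continue
        events.append(
            KinkEvent(
                site=int(rng.choice(sites)),
                start=int(t),
                duration=duration,
                excursion_deg=excursion_deg,
                shape=shape,
            )
        )
        last = t
    return events


# ---------------------------------------------------------------------------
# chain reconstruction (internal coordinates -> Cartesian, NeRF)


def chain_from_angles(
    angles: AngleTrajectory, bond_length: float = CA_CA_BOND_LENGTH
) -> CalphaTrajectory:
    """Rebuild Cα coordinates from a (γ, θ) trajectory.

    Sequential internal-coordinate construction with constant virtual
    bond length: atoms 1–3 are placed in a canonical frame (atom 1 at
    the origin, atom 2 on +x, atom 3 in the xy-plane with positive y),
    and each further atom k follows from atoms k−3..k−1, the bond angle
    θ_{k−1} and the dihedral γ_{k−2}.  The bond angle at residue N−1,
    which no CGA pair carries, is padded with θ_{N−2}; this affects only
    the placement of the last atom in a way that leaves every recoverable
    site angle exact, so angles → chain → angles round-trips to within
    numerical precision.
    """
    n_sites = angles.n_sites
    N = n_sites + 3
    F = angles.n_frames
    g = np.radians(angles.gamma)
    t = np.radians(angles.theta)
    if np.any(t < 1e-6) or np.any(t > np.pi - 1e-6):
        bad = np.argwhere((t < 1e-6) | (t > np.pi - 1e-6))[0]
        site = angles.site_index[bad[1]]
        raise ValueError(
            f"theta at site {site} (frame {bad[0]}) is at a pole; chain placement degenerate"
        )
    b = bond_length
    # bond angle at atom k (0-based col k-1 in theta): theta_i for i=2..N-2,
    # padded at i=N-1 with theta_{N-2}
    theta_full = np.concatenate([t, t[:, -1:]], axis=1)  # angles at residues 2..N-1

    xyz = np.zeros((F, N, 3))
    xyz[:, 1, 0] = b
    th2 = theta_full[:, 0]
    xyz[:, 2, 0] = b - b * np.cos(th2)
    xyz[:, 2, 1] = b * np.sin(th2)
    for k in range(3, N):
        A = xyz[:, k - 3]
        B = xyz[:, k - 2]
        C = xyz[:, k - 1]
        theta_k = theta_full[:, k - 2]  # bond angle at atom k-1 (residue k in 1-based)
        phi_k = g[:, k - 3]  # dihedral of atoms k-3..k (site k-2 in 1-based)
        xyz[:, k] = _nerf_place(A, B, C, b, theta_k, phi_k)
    return CalphaTrajectory(
        coordinates=xyz,
        frame_spacing=angles.frame_spacing,
        residue_names=["GLY"] * N,
    )


def _nerf_place(A, B, C, r, theta, phi):
    """Place D from A, B, C with |CD| = r, angle(B,C,D) = theta, dihedral(A,B,C,D) = phi.

    Sign convention matches :func:`ilmscan.geometry.compute_gamma`
    (cis = 0, package-wide handedness).
    """
    bc = C - B
    bc_hat = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = B - A
    n = np.cross(ab, bc)
    n_hat = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m_hat = np.cross(n_hat, bc_hat)
    ct, st = np.cos(theta)[..., None], np.sin(theta)[..., None]
    cp, sp = np.cos(phi)[..., None], np.sin(phi)[..., None]
    # cis (phi = 0) places D on the A side of the B-C axis
    d = -bc_hat * ct + m_hat * st * cp - n_hat * st * sp
    return C + r * d


def write_trajectory(
    traj: CalphaTrajectory,
    path: str,
    fmt: str = "pdb",
    topology_path: str | None = None,
) -> list[str]:
    """Write a Cα trajectory to standard structural formats.

    ``fmt='pdb'`` emits a single multi-model PDB at ``path``;
    ``fmt='xtc'`` or ``'dcd'`` emit a binary trajectory at ``path`` plus
    a single-frame PDB topology (``topology_path``, default derived from
    ``path``).  Returns the list of files written.  Reading the files
    back through :func:`ilmscan.geometry.load_calpha` reproduces the
    angle series within format precision.
    """
    import MDAnalysis as mda

    fmt = fmt.lower()
    if fmt not in ("pdb", "xtc", "dcd"):
        raise ValueError(f"unsupported format {fmt!r}; supported: pdb, xtc, dcd")
    N = traj.n_residues
    u = mda.Universe.empty(
        n_atoms=N, n_residues=N, atom_resindex=np.arange(N), trajectory=True
    )
    u.add_TopologyAttr("names", ["CA"] * N)
    resnames = traj.residue_names or ["GLY"] * N
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, N + 1))
    u.add_TopologyAttr("elements", ["C"] * N)
    written: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            with mda.Writer(path, n_atoms=N, multiframe=True) as w:
                for f in range(traj.n_frames):
                    u.atoms.positions = traj.coordinates[f]
                    w.write(u.atoms)
            written.append(path)
        else:
            if topology_path is None:
                topology_path = path.rsplit(".", 1)[0] + "_top.pdb"
            u.atoms.positions = traj.coordinates[0]
            with mda.Writer(topology_path, n_atoms=N) as w:
                w.write(u.atoms)
            with mda.Writer(path, n_atoms=N) as w:
                for f in range(traj.n_frames):
                    u.atoms.positions = traj.coordinates[f]
                    u.trajectory.ts.dt = traj.frame_spacing
                    w.write(u.atoms)
            written.extend([topology_path, path])
    return written
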