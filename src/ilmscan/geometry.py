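"""Coarse-grained angle (CGA) geometry of the protein main chain.

The main-chain conformation of a protein is described, at fixed Cα–Cα
virtual bond length, by one pseudo-dihedral angle γ_i (four consecutive
Cα atoms, i−1..i+2) and one pseudo-bond angle θ_i (three consecutive Cα
atoms, i−1..i+1) per residue.  The pair (γ, θ)_i exists for sites
i = 2..N−2 (1-based residue numbering), i.e. N−3 sites for an N-residue
chain.  Each pair maps to a unit vector

    u_i = (cos γ_i sin θ_i, sin γ_i sin θ_i, cos θ_i)

whose inter-frame displacements Δu_i feed the entropy-based localization
detector.

Angles are stored in degrees at the module boundary (γ in (−180, 180],
θ in [0, 180]); radians are used internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "CalphaTrajectory",
    "AngleTrajectory",
    "UnitVectorTrajectory",
    "DisplacementField",
    "compute_theta",
    "compute_gamma",
    "angles_from_trajectory",
    "unit_vectors",
    "displacements",
    "cumulative_displacement",
    "load_calpha",
]

#: Overall handedness of the dihedral.  +1 keeps the standard atan2
#: convention (cis = 0; sign flips under mirror reflection); fixed once
#: for the whole package.
DIHEDRAL_SIGN = 1.0


class DegenerateGeometryError(ValueError):
    """Raised when collinear/coincident Cα atoms make an angle undefined."""


@dataclass
class CalphaTrajectory:
    """Cα coordinates per frame, in Å.

    Parameters
    ----------
    coordinates : ndarray, shape (n_frames, n_residues, 3)
    frame_spacing : float
        Time between saved frames, picoseconds.
    residue_names : list of str, optional
        Three-letter codes, one per residue.
    """

    coordinates: np.ndarray
    frame_spacing: float = 1.0
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_residues, 3)")
        if self.n_residues < 4:
            raise ValueError(
                f"need at least 4 residues for one CGA pair, got {self.n_residues}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class AngleTrajectory:
    """(γ, θ) time series for CGA sites i = 2..N−2.

    gamma, theta : ndarray, shape (n_frames, n_sites), degrees.
    site_index : 1-based residue indices of the sites (2..N−2).
    frame_spacing : picoseconds per frame.
    """

    gamma: np.ndarray
    theta: np.ndarray
    site_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.gamma.shape != self.theta.shape:
            raise ValueError("gamma and theta must share shape")
        if self.gamma.ndim != 2:
            raise ValueError("gamma/theta must be (n_frames, n_sites)")
        if self.site_index is None:
            self.site_index = np.arange(2, 2 + self.n_sites)
        else:
            self.site_index = np.asarray(self.site_index, dtype=int)
            if self.site_index.shape != (self.n_sites,):
                raise ValueError("site_index length must equal n_sites")

    @property
    def n_frames(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_sites(self) -> int:
        return self.gamma.shape[1]

    @property
    def n_residues(self) -> int:
        """Number of residues of the underlying chain (sites + 3)."""
        return self.n_sites + 3

    def site_column(self, site: int) -> int:
        """Column index of residue-site ``site`` (raises if absent)."""
        cols = np.nonzero(self.site_index == site)[0]
        if cols.size == 0:
            raise IndexError(f"site {site} not in trajectory (sites {self.site_index[0]}..{self.site_index[-1]})")
        return int(cols[0])


@dataclass
class UnitVectorTrajectory:
    """Spherical unit vectors u_i per site per frame, shape (n_frames, n_sites, 3)."""

    u: np.ndarray
    site_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[2] != 3:
            raise ValueError("u must be (n_frames, n_sites, 3)")
        if self.site_index is None:
            self.site_index = np.arange(2, 2 + self.n_sites)
        else:
            self.site_index = np.asarray(self.site_index, dtype=int)
        norms = np.linalg.norm(self.u, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("u contains non-unit vectors")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def n_sites(self) -> int:
        return self.u.shape[1]


@dataclass
class DisplacementField:
    """Squared unit-vector displacements Δu_i² on a sliding window.

    du2 : ndarray, shape (n_windows, n_sites); each value is the squared
        chord ‖u_i(t+window) − u_i(t)‖² ∈ [0, 4].
    window : analysis time step Δt in frames (displacement span).
    stride : shift between successive windows, frames.
    start_frames : fine-frame index t of each window start; the
        displacement is attributed to detection frame t + window.
    """

    du2: np.ndarray
    window: int
    stride: int
    start_frames: np.ndarray
    site_index: np.ndarray
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.du2 = np.asarray(self.du2, dtype=float)
        if self.du2.min(initial=0.0) < -1e-12 or self.du2.max(initial=0.0) > 4.0 + 1e-9:
            raise ValueError("du2 out of [0, 4]")

    @property
    def n_windows(self) -> int:
        return self.du2.shape[0]

    @property
    def n_sites(self) -> int:
        return self.du2.shape[1]

    @property
    def detection_frames(self) -> np.ndarray:
        """Fine-frame index each displacement is attributed to (t + window)."""
        return self.start_frames + self.window

    @property
    def times(self) -> np.ndarray:
        """Detection times in the trajectory's time unit (ps)."""
        return self.detection_frames * self.frame_spacing


# ---------------------------------------------------------------------------
# scalar angle operations


def compute_theta(p1, p2, p3) -> float:
    """Pseudo-bond angle at ``p2`` between bonds p2→p1 and p2→p3, degrees in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("coincident points in bond-angle computation")
    c = np.dot(v1, v2) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_gamma(p1, p2, p3, p4) -> float:
    """Pseudo-dihedral of the virtual-bond chain p1–p2–p3–p4, degrees in (−180, 180].

    cis (p1 and p4 on the same side of the p2–p3 bond, planar) is 0°;
    the sign follows the package-wide :data:`DIHEDRAL_SIGN` handedness.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    g = _dihedral_batch(
        p1[None, None], p2[None, None], p3[None, None], p4[None, None]
    )
    return float(g[0, 0])


def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized dihedral (degrees, cis = 0) over leading axes.

    Raises :class:`DegenerateGeometryError` if any triplet is collinear.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1, axis=-1)
    n2n = np.linalg.norm(n2, axis=-1)
    bad = (n1n < 1e-10) | (n2n < 1e-10)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise DegenerateGeometryError(
            f"collinear Cα triplet makes dihedral undefined at (frame, site-column) {tuple(idx)}"
        )
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m = np.cross(n1, b2u)
    x = np.einsum("...k,...k->...", n1, n2)
    y = np.einsum("...k,...k->...", m, n2)
    # the chain p1–p2–p3–p4 cis configuration has n1 ∥ n2 → y = 0, x > 0 → 0°
    return DIHEDRAL_SIGN * np.degrees(np.arctan2(y, x))


def _theta_batch(p1, p2, p3) -> np.ndarray:
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    bad = (n1 < 1e-12) | (n2 < 1e-12)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise DegenerateGeometryError(
            f"coincident Cα atoms at (frame, site-column) {tuple(idx)}"
        )
    c = np.einsum("...k,...k->...", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# trajectory-level operations


def angles_from_trajectory(traj: CalphaTrajectory) -> AngleTrajectory:
    """Compute the (γ, θ) series for sites i = 2..N−2 from Cα coordinates.

    γ_i is the dihedral of Cα(i−1..i+2) and θ_i the bond angle of
    Cα(i−1..i+1); exactly N−3 sites per frame.
    """
    x = traj.coordinates
    n = traj.n_residues
    # site i (1-based) occupies 0-based atoms i-2 .. i+1
    p1 = x[:, 0 : n - 3]
    p2 = x[:, 1 : n - 2]
    p3 = x[:, 2 : n - 1]
    p4 = x[:, 3 : n]
    gamma = _dihedral_batch(p1, p2, p3, p4)
    theta = _theta_batch(p1, p2, p3)
    return AngleTrajectory(
        gamma=gamma,
        theta=theta,
        site_index=np.arange(2, n - 1),
        frame_spacing=traj.frame_spacing,
    )


def unit_vectors(angles: AngleTrajectory) -> UnitVectorTrajectory:
    """Map (γ, θ) to spherical unit vectors (γ azimuth, θ polar)."""
    g = np.radians(angles.gamma)
    t = np.radians(angles.theta)
    st = np.sin(t)
    u = np.stack([np.cos(g) * st, np.sin(g) * st, np.cos(t)], axis=-1)
    return UnitVectorTrajectory(
        u=u, site_index=angles.site_index, frame_spacing=angles.frame_spacing
    )


def displacements(
    u: UnitVectorTrajectory, window: int = 1, stride: int = 1
) -> DisplacementField:
    """Squared displacements Δu_i² = ‖u_i(t+window) − u_i(t)‖² on a sliding window.

    The default window = stride = 1 frame is the consecutive-snapshot
    analysis; window > stride gives the fine-stride multi-resolution
    analysis (e.g. a 1-ps window shifted every fs).
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1 frame")
    if u.n_frames <= window:
        raise ValueError(
            f"trajectory of {u.n_frames} frames too short for window {window}"
        )
    starts = np.arange(0, u.n_frames - window, stride)
    du = u.u[starts + window] - u.u[starts]
    du2 = np.einsum("tsk,tsk->ts", du, du)
    return DisplacementField(
        du2=du2,
        window=window,
        stride=stride,
        start_frames=starts,
        site_index=u.site_index,
        frame_spacing=u.frame_spacing,
    )


def cumulative_displacement(
    u: UnitVectorTrajectory, site: int, t_start: int, t_end: int
) -> np.ndarray:
    """Squared cumulative displacement ‖u_site(t) − u_site(t_start)‖² for t in [t_start, t_end].

    Zero at t_start by construction; ``site`` is the 1-based residue-site
    index.
    """
    if not (0 <= t_start < t_end < u.n_frames):
        raise ValueError("need 0 <= t_start < t_end < n_frames")
    cols = np.nonzero(u.site_index == site)[0]
    if cols.size == 0:
        raise IndexError(f"site {site} out of range")
    col = cols[0]
    ref = u.u[t_start, col]
    du = u.u[t_start : t_end + 1, col] - ref
    return np.einsum("tk,tk->t", du, du)


# ---------------------------------------------------------------------------
# file readers


def load_calpha(
    topology: str,
    trajectory: str | None = None,
    frame_spacing: float | None = None,
    atom_name: str = "CA",
) -> CalphaTrajectory:
    """Read a Cα trajectory from standard structural files.

    Accepts a (multi-model) PDB alone or a PDB topology plus a binary
    trajectory (XTC, DCD, ...); any format MDAnalysis understands works.
    ``frame_spacing`` (ps) overrides whatever the file metadata carries.
    """
    import MDAnalysis as mda

    args = (topology,) if trajectory is None else (topology, trajectory)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(*args)
        ca = universe.select_atoms(f"name {atom_name}")
        if len(ca) < 4:
            raise ValueError(
                f"found {len(ca)} '{atom_name}' atoms; need at least 4"
            )
        coords = np.array([ca.positions.copy() for _ in universe.trajectory])
        if frame_spacing is None:
            frame_spacing = float(getattr(universe.trajectory, "dt", 1.0) or 1.0)
        names = [r.resname for r in ca.residues]
    return CalphaTrajectory(
        coordinates=coords, frame_spacing=frame_spacing, residue_names=names
    )
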