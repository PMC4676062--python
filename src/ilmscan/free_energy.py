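"""Effective free-energy landscapes, native basins, and per-state ILM rates.

For every CGA site the effective free energy over the angle pair is the
Boltzmann inversion of the sampled probability density,

    V(γ, θ) = −k_B T ln P(γ, θ),

reported in k_B T units relative to the occupied minimum (so the global
minimum is 0 and empty bins carry +inf).  A *native basin* is the set of
bins within a depth cutoff (default 3 k_B T) of the minimum of the map
built from a reference (native-state, e.g. 300 K) trajectory.  The
*native character* NC(t) is the percentage of sites whose instantaneous
(γ, θ) falls inside its native basin; a smoothed NC with a threshold and
hysteresis segments a trajectory into native / non-native states, and
soliton-type events are rated per state (events per ns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .entropy import ILMEvent
from .geometry import AngleTrajectory

__all__ = [
    "FreeEnergyMap",
    "NativeBasinMask",
    "NativeCharacterTrace",
    "StateRateTable",
    "free_energy_map",
    "free_energy_profile",
    "native_basins",
    "native_character",
    "state_rates",
]

DEFAULT_GAMMA_BINS = 72  # 5 degree bins, periodic
DEFAULT_THETA_BINS = 36  # 5 degree bins
DEFAULT_BASIN_CUTOFF_KT = 3.0
DEFAULT_NC_THRESHOLD = 80.0
DEFAULT_NC_HYSTERESIS = 5.0


@dataclass
class FreeEnergyMap:
    """2-D free-energy surface V(γ, θ) for one site, k_B T units.

    V is relative to the occupied minimum (min over occupied bins = 0);
    unoccupied bins are +inf.  γ edges span [−180, 180] (periodic axis),
    θ edges [0, 180].
    """

    V: np.ndarray
    gamma_edges: np.ndarray
    theta_edges: np.ndarray
    site_index: int
    reference_temperature: float = 300.0
    counts: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.V.shape


@dataclass
class NativeBasinMask:
    """Boolean per-bin membership of the native basin of one site."""

    mask: np.ndarray
    gamma_edges: np.ndarray
    theta_edges: np.ndarray
    site_index: int
    cutoff_kT: float = DEFAULT_BASIN_CUTOFF_KT


@dataclass
class NativeCharacterTrace:
    """NC(t) in percent, its moving average, and the per-frame state label."""

    NC: np.ndarray
    smoothed_NC: np.ndarray
    state_label: np.ndarray  # "native" | "non_native" per frame
    smoothing_window: int
    threshold_NC: float
    hysteresis: float
    frame_spacing: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.NC.shape[0]


@dataclass
class StateRateTable:
    """Soliton counts, state durations (ns) and rates (events/ns) per state.

    Mirrors the native/non-native rate bookkeeping: t_n/t_nn are the
    durations, N_n/N_nn the soliton counts (terminal-class events are
    excluded upstream), P_n/P_nn the rates, and ratio = P_nn/P_n.
    ``ratio`` is exact; :meth:`printed` applies the publication-style
    convention of rounding the rates to 3 decimals before forming their
    ratio.
    """

    t_n: float
    t_nn: float
    N_n: int
    N_nn: int

    @property
    def P_n(self) -> float:
        if self.t_n <= 0:
            return float("nan")
        return self.N_n / self.t_n

    @property
    def P_nn(self) -> float:
        if self.t_nn <= 0:
            return float("nan")
        return self.N_nn / self.t_nn

    @property
    def ratio(self) -> float:
        """Exact P_nn / P_n; inf when the native rate is 0."""
        pn, pnn = self.P_n, self.P_nn
        if np.isnan(pn) or np.isnan(pnn):
            return float("nan")
        if pn == 0:
            return float("inf")
        return pnn / pn

    @property
    def ratio_is_infinite(self) -> bool:
        return self.N_n == 0 and self.t_n > 0 and self.N_nn > 0

    def printed(self, decimals: int = 3) -> dict:
        """Rates rounded to ``decimals`` and the ratio of the rounded rates.

        This is the convention that reproduces published rate tables in
        which the ratio column follows from the rounded rate columns.
        """
        pn = round(self.P_n, decimals) if self.t_n > 0 else None
        pnn = round(self.P_nn, decimals) if self.t_nn > 0 else None
        if pn and pnn is not None:
            ratio = round(pnn / pn, 1)
        elif pn == 0 and pnn:
            ratio = float("inf")
        else:
            ratio = None
        return {
            "t_n": self.t_n,
            "t_nn": self.t_nn,
            "N_n": self.N_n,
            "N_nn": self.N_nn,
            "P_n": pn,
            "P_nn": pnn,
            "ratio": ratio,
        }

    def to_json(self, path=None, decimals: int = 3) -> str:
        payload = self.printed(decimals)
        payload["ratio_exact"] = None if np.isnan(self.ratio) else (
            "inf" if np.isinf(self.ratio) else self.ratio
        )
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------


def _default_edges(gamma_bins: int, theta_bins: int):
    return (
        np.linspace(-180.0, 180.0, gamma_bins + 1),
        np.linspace(0.0, 180.0, theta_bins + 1),
    )


def free_energy_map(
    angles: AngleTrajectory,
    site: int,
    gamma_bins: int = DEFAULT_GAMMA_BINS,
    theta_bins: int = DEFAULT_THETA_BINS,
    temperature: float = 300.0,
) -> FreeEnergyMap:
    """Boltzmann-invert the 2-D (γ, θ) histogram of one site into V(γ, θ).

    V = −ln(P / P_max) in k_B T units at the given temperature; empty
    bins are +inf.  Fewer than 1000 frames triggers a sampling warning.
    """
    if angles.n_frames == 0:
        raise ValueError("empty trajectory")
    if angles.n_frames < 1000:
        import warnings

        warnings.warn(
            f"only {angles.n_frames} frames; free-energy map will be noisy",
            stacklevel=2,
        )
    col = angles.site_column(site)
    g = _wrap_gamma(angles.gamma[:, col])
    t = angles.theta[:, col]
    ge, te = _default_edges(gamma_bins, theta_bins)
    counts, _, _ = np.histogram2d(g, t, bins=[ge, te])
    return _map_from_counts(counts, ge, te, site, temperature)


def _map_from_counts(counts, ge, te, site, temperature) -> FreeEnergyMap:
    V = np.full(counts.shape, np.inf)
    occ = counts > 0
    if not occ.any():
        raise ValueError("no occupied bins")
    V[occ] = -np.log(counts[occ] / counts.max())
    return FreeEnergyMap(
        V=V,
        gamma_edges=ge,
        theta_edges=te,
        site_index=site,
        reference_temperature=temperature,
        counts=counts,
    )


def free_energy_profile(
    angles: AngleTrajectory,
    site: int,
    which: str = "gamma",
    bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """1-D free-energy profile V(γ) or V(θ) for one site, k_B T units.

    Returns (V, bin_edges); V relative to the occupied minimum, empty
    bins +inf.
    """
    col = angles.site_column(site)
    if which == "gamma":
        x = _wrap_gamma(angles.gamma[:, col])
        edges = np.linspace(-180.0, 180.0, (bins or DEFAULT_GAMMA_BINS) + 1)
    elif which == "theta":
        x = angles.theta[:, col]
        edges = np.linspace(0.0, 180.0, (bins or DEFAULT_THETA_BINS) + 1)
    else:
        raise ValueError("which must be 'gamma' or 'theta'")
    counts, _ = np.histogram(x, bins=edges)
    V = np.full(counts.shape, np.inf)
    occ = counts > 0
    V[occ] = -np.log(counts[occ] / counts.max())
    return V, edges


def _wrap_gamma(g: np.ndarray) -> np.ndarray:
    """Wrap γ into [−180, 180) so the periodic histogram axis is well posed."""
    return (np.asarray(g, dtype=float) + 180.0) % 360.0 - 180.0


def native_basins(
    fmap: FreeEnergyMap,
    cutoff_kT: float = DEFAULT_BASIN_CUTOFF_KT,
    connected_only: bool = False,
) -> NativeBasinMask:
    """Bins within ``cutoff_kT`` of the map's minimum.

    By default the whole sub-level set {V ≤ cutoff} counts, whether or
    not contiguous with the global minimum; ``connected_only`` keeps
    only the connected component containing the minimum (γ-periodic
    connectivity).
    """
    V = fmap.V
    mask = V <= cutoff_kT
    if connected_only and mask.any():
        from scipy import ndimage

        lab, _ = ndimage.label(mask)
        # stitch components split by the periodic gamma seam
        first, last = lab[0, :], lab[-1, :]
        for a, b in zip(first, last):
            if a > 0 and b > 0 and a != b:
                lab[lab == b] = a
        gmin = np.unravel_index(np.argmin(np.where(np.isfinite(V), V, np.inf)), V.shape)
        mask = lab == lab[gmin]
    return NativeBasinMask(
        mask=mask,
        gamma_edges=fmap.gamma_edges,
        theta_edges=fmap.theta_edges,
        site_index=fmap.site_index,
        cutoff_kT=cutoff_kT,
    )


def _bin_indices(values, edges, periodic_span=None):
    """Bin column for each value; clips the last edge into the last bin."""
    v = np.asarray(values, dtype=float)
    if periodic_span is not None:
        v = (v - edges[0]) % periodic_span + edges[0]
    idx = np.searchsorted(edges, v, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def native_character(
    angles: AngleTrajectory,
    masks: dict[int, NativeBasinMask] | list[NativeBasinMask],
    smoothing_window: int | None = None,
    smoothing_time: float | None = None,
    threshold_NC: float = DEFAULT_NC_THRESHOLD,
    hysteresis: float = DEFAULT_NC_HYSTERESIS,
) -> NativeCharacterTrace:
    """NC(t): % of CGA sites inside their native basins, smoothed and labeled.

    ``smoothing_window`` is in analysis frames (``smoothing_time`` in ps
    may be given instead; default 1 ns worth of frames).  Frames are
    labeled native while the smoothed NC stays at or above
    ``threshold_NC``; the label flips to non-native only when it drops
    below ``threshold_NC − hysteresis`` (and back at ``threshold_NC``),
    which prevents chattering at the boundary.
    """
    if isinstance(masks, dict):
        mask_by_site = masks
    else:
        mask_by_site = {m.site_index: m for m in masks}
    missing = [s for s in angles.site_index if s not in mask_by_site]
    if missing:
        raise ValueError(f"no native-basin mask for sites {missing}")

    inside = np.zeros((angles.n_frames, angles.n_sites), dtype=bool)
    for col, site in enumerate(angles.site_index):
        m = mask_by_site[site]
        gi = _bin_indices(angles.gamma[:, col], m.gamma_edges, periodic_span=360.0)
        ti = _bin_indices(angles.theta[:, col], m.theta_edges)
        inside[:, col] = m.mask[gi, ti]
    NC = 100.0 * inside.mean(axis=1)

    if smoothing_window is None:
        if smoothing_time is None:
            smoothing_time = 1000.0  # 1 ns in ps
        smoothing_window = max(1, int(round(smoothing_time / angles.frame_spacing)))
    smoothed = _centered_moving_average(NC, smoothing_window)

    label = np.empty(NC.shape[0], dtype=object)
    native = smoothed[0] >= threshold_NC
    lower = threshold_NC - hysteresis
    for k in range(NC.shape[0]):
        if native and smoothed[k] < lower:
            native = False
        elif not native and smoothed[k] >= threshold_NC:
            native = True
        label[k] = "native" if native else "non_native"
    return NativeCharacterTrace(
        NC=NC,
        smoothed_NC=smoothed,
        state_label=label,
        smoothing_window=smoothing_window,
        threshold_NC=threshold_NC,
        hysteresis=hysteresis,
        frame_spacing=angles.frame_spacing,
    )


def _centered_moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.copy()
    # shrinking window at the edges keeps the trace length and avoids bias
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.shape[0]
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def state_rates(
    nc: NativeCharacterTrace,
    events: list[ILMEvent],
) -> StateRateTable:
    """Per-state soliton rates from an NC trace and a detected event list.

    Soliton-class events are assigned to the state label at their
    detection frame; terminal-class events are excluded.  Durations are
    state frame counts × frame spacing, converted to ns; rates are
    events per ns.
    """
    n_native = int(np.sum(nc.state_label == "native"))
    n_non = nc.n_frames - n_native
    ps_to_ns = 1e-3
    t_n = n_native * nc.frame_spacing * ps_to_ns
    t_nn = n_non * nc.frame_spacing * ps_to_ns
    N_n = N_nn = 0
    for ev in events:
        if ev.event_class != "soliton":
            continue
        k = min(ev.frame, nc.n_frames - 1)
        if nc.state_label[k] == "native":
            N_n += 1
        else:
            N_nn += 1
    return StateRateTable(t_n=t_n, t_nn=t_nn, N_n=N_n, N_nn=N_nn)
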