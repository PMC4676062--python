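"""Normalized Shannon-entropy localization statistic and ILM detection.

Each analysis frame distributes the main-chain fluctuation over the M =
N−3 CGA sites through the shares

    p_i(t) = Δu_i(t)² / Σ_j Δu_j(t)²,

and the degree of localization is the normalized Shannon entropy

    S(t) = −Σ_i p_i ln p_i / ln M,   0 ≤ S ≤ 1,

with S = 0 for a fluctuation concentrated on a single site and S = 1 for
a perfectly uniform one.  Intrinsic localized modes (ILMs) are the rare
frames with S at or below a cutoff (default 0.5); the cutoff can be
calibrated by requiring that all event amplitude profiles localized at
the same site be strongly correlated (ρ > 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AngleTrajectory, DisplacementField

__all__ = [
    "EntropyTrace",
    "ILMEvent",
    "CutoffCalibration",
    "shares_and_entropy",
    "detect_ilms",
    "calibrate_cutoff",
    "classify_event",
    "label_transition",
    "entropy_distribution",
    "event_lifetime",
    "profile_entropy",
    "circular_mean_deg",
]

DEFAULT_CUTOFF = 0.5
DEFAULT_RHO_MIN = 0.9
DEFAULT_CUTOFF_GRID = (0.40, 0.45, 0.50, 0.55, 0.60)
CIS_BAND_DEG = 60.0
TRANS_BAND_DEG = 120.0


@dataclass
class EntropyTrace:
    """Per-frame localization entropy S and site shares p_i.

    S is NaN for frames whose total displacement is exactly zero (the
    shares are then 0/0 and the entropy undefined; such frames are
    treated as missing, never as 0 or 1).
    """

    S: np.ndarray
    p: np.ndarray
    window: int
    stride: int
    start_frames: np.ndarray
    site_index: np.ndarray
    frame_spacing: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.S.shape[0]

    @property
    def n_sites(self) -> int:
        return self.p.shape[1]

    @property
    def detection_frames(self) -> np.ndarray:
        return self.start_frames + self.window

    @property
    def times(self) -> np.ndarray:
        return self.detection_frames * self.frame_spacing

    @property
    def stride_time(self) -> float:
        """Time between successive analysis frames, ps."""
        return self.stride * self.frame_spacing


@dataclass
class ILMEvent:
    """One detected localized excitation.

    frame is the fine-frame detection index (window start + window);
    site the 1-based residue-site index of the amplitude maximum;
    amplitude the Δu² at that site; profile the Δu_i² over all sites at
    the detection frame.  n_merged counts the contiguous sub-cutoff
    analysis frames merged into this event.
    """

    frame: int
    time: float
    site: int
    S_value: float
    amplitude: float
    profile: np.ndarray
    event_class: str = "soliton"  # soliton | terminal
    transition: str = "none"  # cis_to_trans | trans_to_cis | none
    trace_index: int = -1
    n_merged: int = 1

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)


@dataclass
class CutoffCalibration:
    """Result of the profile-correlation cutoff calibration."""

    candidates: np.ndarray
    min_correlation: np.ndarray  # per candidate; NaN when no site had >= 2 events
    passed: np.ndarray  # bool per candidate
    selected: float
    inconclusive: bool = False
    rho_min: float = DEFAULT_RHO_MIN


def shares_and_entropy(d: DisplacementField) -> EntropyTrace:
    """Compute p_i(t) and the normalized Shannon entropy S(t).

    Terms with p_i = 0 contribute nothing to the sum; frames with zero
    total displacement get S = NaN (masked).
    """
    if d.n_sites < 2:
        raise ValueError("need at least 2 sites for a normalized entropy")
    total = d.du2.sum(axis=1)
    ok = total > 0
    p = np.full_like(d.du2, np.nan)
    p[ok] = d.du2[ok] / total[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.full(d.n_windows, np.nan)
    S[ok] = -plogp[ok].sum(axis=1) / np.log(d.n_sites)
    # clip away roundoff just outside [0, 1]; + 0.0 normalizes -0.0
    S[ok] = np.clip(S[ok], 0.0, 1.0) + 0.0
    return EntropyTrace(
        S=S,
        p=p,
        window=d.window,
        stride=d.stride,
        start_frames=d.start_frames,
        site_index=d.site_index,
        frame_spacing=d.frame_spacing,
    )


def detect_ilms(
    trace: EntropyTrace,
    d: DisplacementField,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ILMEvent]:
    """Detect ILM events: analysis frames with S ≤ cutoff.

    The event site is the argmax of p_i.  Qualifying frames at the same
    site whose detection frames lie within one window length of the
    previous qualifying frame are merged into a single event, keeping
    the minimal-S frame (a fine-stride analysis would otherwise count
    one physical excitation many times).  Events are classified as
    terminal (first/last CGA site) or soliton.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        hits = np.nonzero(trace.S <= cutoff)[0]
    events: list[ILMEvent] = []
    det = trace.detection_frames
    n_sites = trace.n_sites
    prev_site = None
    prev_frame = None
    for k in hits:
        site_col = int(np.argmax(trace.p[k]))
        site = int(trace.site_index[site_col])
        frame = int(det[k])
        merged = (
            prev_site == site
            and prev_frame is not None
            and frame - prev_frame <= trace.window
        )
        if merged:
            ev = events[-1]
            ev.n_merged += 1
            if trace.S[k] < ev.S_value:
                ev.frame = frame
                ev.time = frame * trace.frame_spacing
                ev.S_value = float(trace.S[k])
                ev.amplitude = float(d.du2[k, site_col])
                ev.profile = d.du2[k].copy()
                ev.trace_index = int(k)
        else:
            ev = ILMEvent(
                frame=frame,
                time=frame * trace.frame_spacing,
                site=site,
                S_value=float(trace.S[k]),
                amplitude=float(d.du2[k, site_col]),
                profile=d.du2[k].copy(),
                trace_index=int(k),
            )
            ev.event_class = classify_event(ev, n_sites, trace.site_index)
            events.append(ev)
        prev_site = site
        prev_frame = frame
    return events


def classify_event(
    event: ILMEvent, n_sites: int, site_index: np.ndarray | None = None
) -> str:
    """Terminal if the event sits on the first or last CGA site, else soliton.

    End-of-chain excitations exist even in a harmonic chain with free
    ends (broken translational symmetry) and are not sine-Gordon-like.
    """
    if site_index is None:
        site_index = np.arange(2, 2 + n_sites)
    first, last = int(site_index[0]), int(site_index[-1])
    if event.site not in site_index:
        raise ValueError(f"event site {event.site} outside chain sites {first}..{last}")
    return "terminal" if event.site in (first, last) else "soliton"


def calibrate_cutoff(
    trace: EntropyTrace,
    d: DisplacementField,
    candidates=DEFAULT_CUTOFF_GRID,
    rho_min: float = DEFAULT_RHO_MIN,
    mode: str = "reference",
) -> CutoffCalibration:
    """Choose the entropy cutoff by profile-correlation consistency.

    For each candidate cutoff, events are collected per site; at every
    site with ≥ 2 events the Pearson correlation of each event's Δu_i²
    profile is computed against the maximal-amplitude event at that site
    (``mode="reference"``) or over all pairs (``mode="pairwise"``).  A
    candidate passes when every such correlation exceeds ``rho_min``;
    the largest passing candidate is selected.  If no candidate yields
    any site with ≥ 2 events the calibration is inconclusive and the
    default cutoff 0.5 is returned with a flag.
    """
    candidates = np.asarray(sorted(candidates), dtype=float)
    if not (0.0 < rho_min < 1.0):
        raise ValueError("rho_min must lie in (0, 1)")
    if mode not in ("reference", "pairwise"):
        raise ValueError("mode must be 'reference' or 'pairwise'")
    min_rho = np.full(candidates.size, np.nan)
    passed = np.zeros(candidates.size, dtype=bool)
    any_multi = False
    for ci, c in enumerate(candidates):
        events = detect_ilms(trace, d, cutoff=float(c))
        by_site: dict[int, list[ILMEvent]] = {}
        for ev in events:
            by_site.setdefault(ev.site, []).append(ev)
        rhos: list[float] = []
        for evs in by_site.values():
            if len(evs) < 2:
                continue
            any_multi = True
            profiles = np.array([e.profile for e in evs])
            if mode == "reference":
                ref = profiles[int(np.argmax([e.amplitude for e in evs]))]
                for k in range(len(evs)):
                    if not np.array_equal(profiles[k], ref):
                        rhos.append(_pearson(profiles[k], ref))
            else:
                for a in range(len(evs)):
                    for b in range(a + 1, len(evs)):
                        rhos.append(_pearson(profiles[a], profiles[b]))
        if rhos:
            min_rho[ci] = min(rhos)
            passed[ci] = min_rho[ci] > rho_min
        else:
            passed[ci] = True  # vacuous: no site constrains this candidate
    if not any_multi:
        return CutoffCalibration(
            candidates=candidates,
            min_correlation=min_rho,
            passed=passed,
            selected=DEFAULT_CUTOFF,
            inconclusive=True,
            rho_min=rho_min,
        )
    winners = candidates[passed]
    selected = float(winners.max()) if winners.size else float(candidates.min())
    return CutoffCalibration(
        candidates=candidates,
        min_correlation=min_rho,
        passed=passed,
        selected=selected,
        inconclusive=False,
        rho_min=rho_min,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.dot(a, b) / denom)


def profile_entropy(du2_profile: np.ndarray) -> float:
    """Normalized Shannon entropy of a single Δu² profile over M sites.

    Convenience for static profiles (e.g. a sine-Gordon kink snapshot);
    equivalent to :func:`shares_and_entropy` on a one-frame field.
    """
    du2 = np.asarray(du2_profile, dtype=float)
    if du2.ndim != 1 or du2.size < 2:
        raise ValueError("profile must be 1-D with at least 2 sites")
    total = du2.sum()
    if total <= 0:
        raise ValueError("zero total displacement: entropy undefined")
    p = du2 / total
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(np.clip(-plogp.sum() / np.log(du2.size), 0.0, 1.0))


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees via vector averaging, in (−180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    m = np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))
    return float(m if m > -180.0 else 180.0)


def label_transition(
    angles: AngleTrajectory,
    event: ILMEvent,
    pre_window: int = 5,
    post_window: int = 5,
    cis_band: float = CIS_BAND_DEG,
    trans_band: float = TRANS_BAND_DEG,
) -> str:
    """Label an event as a cis↔trans rotation of its four-Cα segment.

    The circular-mean γ at the event site is computed over ``pre_window``
    frames before the detection frame and ``post_window`` frames after.
    |γ| < cis_band counts as cis, |γ| > trans_band as trans; anything
    else (incomplete rotations, barrier-top jumps) labels ``none``.
    """
    col = angles.site_column(event.site)
    f = event.frame
    lo = f - pre_window
    hi = f + post_window
    if lo < 0 or hi >= angles.n_frames:
        raise ValueError("pre/post windows do not fit inside the trajectory")
    pre = circular_mean_deg(angles.gamma[lo:f, col])
    post = circular_mean_deg(angles.gamma[f + 1 : hi + 1, col])

    def region(g: float) -> str:
        if abs(g) < cis_band:
            return "cis"
        if abs(g) > trans_band:
            return "trans"
        return "mid"

    r0, r1 = region(pre), region(post)
    if r0 == "cis" and r1 == "trans":
        return "cis_to_trans"
    if r0 == "trans" and r1 == "cis":
        return "trans_to_cis"
    return "none"


def entropy_distribution(
    trace: EntropyTrace, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density P(S) over [0, 1]; missing-S frames excluded.

    Returns (density, bin_edges) as from ``numpy.histogram(density=True)``.
    Traces computed at different windows can be overlaid by calling this
    with the same ``n_bins``.
    """
    s = trace.S[np.isfinite(trace.S)]
    if s.size == 0:
        raise ValueError("entropy trace is empty (or all frames masked)")
    density, edges = np.histogram(s, bins=n_bins, range=(0.0, 1.0), density=True)
    return density, edges


def event_lifetime(
    trace: EntropyTrace, event: ILMEvent, cutoff: float = DEFAULT_CUTOFF
) -> float:
    """Lifetime of an event: span of the maximal contiguous S ≤ cutoff run.

    Meaningful on fine-stride traces (stride ≪ window).  Returns the run
    length times the stride time (ps); a single qualifying frame counts
    one stride.
    """
    k = event.trace_index
    if k < 0 or k >= trace.n_frames:
        raise ValueError("event does not reference a frame of this trace")
    with np.errstate(invalid="ignore"):
        below = trace.S <= cutoff
    if not below[k]:
        raise ValueError(
            f"event frame has S = {trace.S[k]:.3f}, above cutoff {cutoff}"
        )
    lo = k
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = k
    while hi < trace.n_frames - 1 and below[hi + 1]:
        hi += 1
    return (hi - lo + 1) * trace.stride_time
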