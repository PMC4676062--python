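"""Tabular import/export of angle series, entropy traces, events and maps.

The internal exchange format for angles is a long-form columnar table
(frame, site, gamma_deg, theta_deg), written either as CSV or as a
compact HDF5 store for long trajectories.  Event reports and NC traces
are plain CSV/JSON so they are easy to post-process.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .entropy import EntropyTrace, ILMEvent
from .free_energy import FreeEnergyMap, NativeCharacterTrace
from .geometry import AngleTrajectory

__all__ = [
    "angles_to_frame",
    "write_angles_csv",
    "read_angles_csv",
    "write_angles_h5",
    "read_angles_h5",
    "events_to_frame",
    "write_events",
    "trace_to_frame",
    "write_entropy_trace",
    "nc_to_frame",
    "write_nc_trace",
    "write_map_h5",
]


def angles_to_frame(angles: AngleTrajectory) -> pd.DataFrame:
    """Long-form table with columns (frame, site, gamma_deg, theta_deg)."""
    F, M = angles.n_frames, angles.n_sites
    return pd.DataFrame(
        {
            "frame": np.repeat(np.arange(F), M),
            "site": np.tile(angles.site_index, F),
            "gamma_deg": angles.gamma.ravel(),
            "theta_deg": angles.theta.ravel(),
        }
    )


def write_angles_csv(angles: AngleTrajectory, path: str) -> None:
    angles_to_frame(angles).to_csv(path, index=False)


def read_angles_csv(path: str, frame_spacing: float = 1.0) -> AngleTrajectory:
    df = pd.read_csv(path)
    sites = np.sort(df["site"].unique())
    F = df["frame"].nunique()
    df = df.sort_values(["frame", "site"])
    return AngleTrajectory(
        gamma=df["gamma_deg"].to_numpy().reshape(F, sites.size),
        theta=df["theta_deg"].to_numpy().reshape(F, sites.size),
        site_index=sites,
        frame_spacing=frame_spacing,
    )


def write_angles_h5(angles: AngleTrajectory, path: str) -> None:
    """Compact binary store for long trajectories."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("gamma_deg", data=angles.gamma, compression="gzip")
        h5.create_dataset("theta_deg", data=angles.theta, compression="gzip")
        h5.create_dataset("site_index", data=angles.site_index)
        h5.attrs["frame_spacing_ps"] = angles.frame_spacing


def read_angles_h5(path: str) -> AngleTrajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        return AngleTrajectory(
            gamma=h5["gamma_deg"][()],
            theta=h5["theta_deg"][()],
            site_index=h5["site_index"][()],
            frame_spacing=float(h5.attrs["frame_spacing_ps"]),
        )


def events_to_frame(events: list[ILMEvent]) -> pd.DataFrame:
    cols = ["time", "frame", "site", "S", "amplitude", "class", "transition", "n_merged"]
    rows = [
        (ev.time, ev.frame, ev.site, ev.S_value, ev.amplitude, ev.event_class,
         ev.transition, ev.n_merged)
        for ev in events
    ]
    return pd.DataFrame(rows, columns=cols)


def write_events(events: list[ILMEvent], path: str) -> None:
    """CSV or JSON event report, by file extension."""
    df = events_to_frame(events)
    if path.endswith(".json"):
        df.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, index=False)


def trace_to_frame(trace: EntropyTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {"time": trace.times, "frame": trace.detection_frames, "S": trace.S}
    )


def write_entropy_trace(trace: EntropyTrace, path: str) -> None:
    trace_to_frame(trace).to_csv(path, index=False)


def nc_to_frame(nc: NativeCharacterTrace) -> pd.DataFrame:
    t = np.arange(nc.n_frames) * nc.frame_spacing
    return pd.DataFrame(
        {
            "time": t,
            "NC": nc.NC,
            "smoothed_NC": nc.smoothed_NC,
            "state": nc.state_label,
        }
    )


def write_nc_trace(nc: NativeCharacterTrace, path: str) -> None:
    nc_to_frame(nc).to_csv(path, index=False)


def write_map_h5(fmap: FreeEnergyMap, path: str, mask=None) -> None:
    """Dense free-energy grid with bin-edge metadata (optionally the basin mask)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("V_kT", data=fmap.V)
        h5.create_dataset("gamma_edges_deg", data=fmap.gamma_edges)
        h5.create_dataset("theta_edges_deg", data=fmap.theta_edges)
        if fmap.counts is not None:
            h5.create_dataset("counts", data=fmap.counts)
        if mask is not None:
            h5.create_dataset("native_mask", data=np.asarray(mask.mask))
            h5.attrs["basin_cutoff_kT"] = mask.cutoff_kT
        h5.attrs["site_index"] = fmap.site_index
        h5.attrs["reference_temperature_K"] = fmap.reference_temperature
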