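"""Readers and writers for the package's file formats.

Arrays and fields travel as HDF5 (axes in metres, pressures in Pa,
temperatures in degC); metric tables as CSV; run manifests as JSON with
SHA-256 content hashes.  Spike and lick tables are plain delimited text so
they can be inspected and produced by other tools.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acoustics import BeamMetrics, FieldGrid, PressureField
from .behavior import LickSession
from .neural import EcogRecording, SpikeTrainSet

__all__ = [
    "write_pressure_field",
    "read_pressure_field",
    "write_beam_metrics",
    "read_beam_metrics",
    "write_spike_set",
    "read_spike_set",
    "write_ecog",
    "read_ecog",
    "write_lick_sessions",
    "read_lick_sessions",
    "write_manifest",
    "sha256_of",
]


def write_pressure_field(path: str | Path, field: PressureField) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=field.grid.x)
        f.create_dataset("y", data=field.grid.y)
        f.create_dataset("z", data=field.grid.z)
        f.create_dataset("amplitude", data=field.amplitude)
        f.attrs["frequency"] = field.frequency
        f.attrs["units"] = "m, Pa, Hz"
    return path


def read_pressure_field(path: str | Path) -> PressureField:
    with h5py.File(path, "r") as f:
        grid = FieldGrid(x=f["x"][:], y=f["y"][:], z=f["z"][:])
        return PressureField(
            grid=grid,
            amplitude=f["amplitude"][:],
            frequency=float(f.attrs["frequency"]),
        )


def write_beam_metrics(path: str | Path, metrics: dict[str, BeamMetrics]) -> Path:
    path = Path(path)
    rows = [
        {
            "preset": name,
            "lateral_fwhm_mm": m.lateral_fwhm * 1e3,
            "axial_fwhm_mm": m.axial_fwhm * 1e3,
            "peak_depth_mm": m.peak_depth * 1e3,
            "peak_pressure_pa": m.peak_pressure,
        }
        for name, m in metrics.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_beam_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spike_set(prefix: str | Path, spikes: SpikeTrainSet) -> tuple[Path, Path]:
    """Write ``<prefix>_spikes.csv`` and ``<prefix>_positions.csv``."""
    prefix = Path(prefix)
    spikes_path = prefix.with_name(prefix.name + "_spikes.csv")
    pos_path = prefix.with_name(prefix.name + "_positions.csv")
    spikes.spikes.to_csv(spikes_path, index=False)
    spikes.positions.assign(n_trials=spikes.n_trials).to_csv(pos_path, index=False)
    return spikes_path, pos_path


def read_spike_set(spikes_csv: str | Path, positions_csv: str | Path) -> SpikeTrainSet:
    spikes = pd.read_csv(spikes_csv)
    pos = pd.read_csv(positions_csv)
    n_trials = int(pos["n_trials"].iloc[0]) if "n_trials" in pos else int(
        spikes["trial"].max() + 1
    )
    return SpikeTrainSet(
        spikes=spikes,
        positions=pos[["cell", "x", "y"]],
        n_trials=n_trials,
    )


def write_ecog(path: str | Path, rec: EcogRecording) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("trial_onsets", data=rec.trial_onsets)
        f.create_dataset("channel", data=rec.positions["channel"].to_numpy())
        f.create_dataset("x", data=rec.positions["x"].to_numpy())
        f.create_dataset("y", data=rec.positions["y"].to_numpy())
        f.attrs["fs"] = rec.fs
        f.attrs["units"] = "V, s, m"
    return path


def read_ecog(path: str | Path) -> EcogRecording:
    with h5py.File(path, "r") as f:
        positions = pd.DataFrame(
            {"channel": f["channel"][:], "x": f["x"][:], "y": f["y"][:]}
        )
        return EcogRecording(
            data=f["data"][:],
            fs=float(f.attrs["fs"]),
            positions=positions,
            trial_onsets=f["trial_onsets"][:],
        )


def write_lick_sessions(path: str | Path, sessions: list[LickSession]) -> Path:
    """All sessions in one long-format CSV (trial rows and lick rows)."""
    path = Path(path)
    frames = []
    for s in sessions:
        meta = {
            "animal_id": s.animal_id,
            "day": s.day,
            "stimulus_type": s.stimulus_type,
            "pressure": s.pressure,
            "reward_delay": s.reward_delay,
        }
        frames.append(
            pd.DataFrame({**meta, "kind": "trial", "time": s.trial_onsets})
        )
        frames.append(pd.DataFrame({**meta, "kind": "lick", "time": s.lick_times}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_lick_sessions(path: str | Path) -> list[LickSession]:
    df = pd.read_csv(path)
    sessions = []
    keys = ["animal_id", "day", "stimulus_type", "pressure", "reward_delay"]
    for vals, sub in df.groupby(keys, sort=True):
        meta = dict(zip(keys, vals))
        sessions.append(
            LickSession(
                animal_id=str(meta["animal_id"]),
                day=int(meta["day"]),
                stimulus_type=str(meta["stimulus_type"]),
                pressure=float(meta["pressure"]),
                trial_onsets=sub.loc[sub["kind"] == "trial", "time"].to_numpy(),
                lick_times=sub.loc[sub["kind"] == "lick", "time"].to_numpy(),
                reward_delay=float(meta["reward_delay"]),
            )
        )
    return sessions


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
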