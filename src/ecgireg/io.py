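"""Serialization: HDF5 beat container, delimited-text matrices, configs.

Dataset layout (HDF5)::

    /geometry/{heart_nodes, torso_electrodes, recording_electrodes,
               electrode_node_map}
    /transfer/A
    /beats/<k>/{B, H_true, at_true, rt_true}     (+ per-beat attrs)

Every array dataset carries a ``units`` attribute (mm, mV, ms or
dimensionless).  Transfer matrices can also round-trip through CSV with
a ``# n_body,n_heart`` header for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .selection import SelectionResult
from .synthetic import Dataset, DatasetConfig, Geometry, GroundTruthBeat
from .tikhonov import BeatRecording

__all__ = [
    "save_dataset", "load_dataset",
    "write_transfer_csv", "read_transfer_csv",
    "write_selection", "read_selection",
    "load_config", "save_config",
]


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(dataset.config.to_dict())
        g = f.create_group("geometry")
        for name, units in [
            ("heart_nodes", "mm"), ("torso_electrodes", "mm"),
            ("recording_electrodes", "mm"),
        ]:
            d = g.create_dataset(name, data=getattr(dataset.geometry, name))
            d.attrs["units"] = units
        d = g.create_dataset(
            "electrode_node_map", data=dataset.geometry.electrode_node_map
        )
        d.attrs["units"] = "index"
        d = f.create_group("transfer").create_dataset("A", data=dataset.A)
        d.attrs["units"] = "dimensionless"
        beats = f.create_group("beats")
        for k, (rec, gt) in enumerate(dataset.beats):
            bg = beats.create_group(str(k))
            for name, arr, units in [
                ("B", rec.B, "mV"), ("H_true", gt.H_true, "mV"),
                ("at_true", gt.at_true, "ms"), ("rt_true", gt.rt_true, "ms"),
            ]:
                d = bg.create_dataset(name, data=arr)
                d.attrs["units"] = units
            bg.attrs.update({
                "fs": gt.fs, "pacing_node": gt.pacing_node,
                "qrs_window": gt.qrs_window, "t_window": gt.t_window,
                "snr_db": gt.snr_db,
                "seed": -1 if gt.seed is None else gt.seed,
            })


def load_dataset(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as f:
        config = DatasetConfig.from_dict(json.loads(f.attrs["config"]))
        g = f["geometry"]
        geom = Geometry(
            heart_nodes=g["heart_nodes"][()],
            torso_electrodes=g["torso_electrodes"][()],
            recording_electrodes=g["recording_electrodes"][()],
            electrode_node_map=g["electrode_node_map"][()],
        )
        A = f["transfer/A"][()]
        beats = []
        keys = sorted(f["beats"], key=int)
        for k in keys:
            bg = f["beats"][k]
            qrs = tuple(int(v) for v in bg.attrs["qrs_window"])
            tw = tuple(int(v) for v in bg.attrs["t_window"])
            fs = float(bg.attrs["fs"])
            rec = BeatRecording(B=bg["B"][()], fs=fs, qrs_window=qrs, t_window=tw)
            seed = int(bg.attrs["seed"])
            gt = GroundTruthBeat(
                H_true=bg["H_true"][()], at_true=bg["at_true"][()],
                rt_true=bg["rt_true"][()],
                pacing_node=int(bg.attrs["pacing_node"]), fs=fs,
                qrs_window=qrs, t_window=tw,
                seed=None if seed < 0 else seed,
                snr_db=float(bg.attrs["snr_db"]),
            )
            beats.append((rec, gt))
    return Dataset(config=config, geometry=geom, A=A, beats=beats)


def write_transfer_csv(A: np.ndarray, path: str | Path) -> None:
    """Row-major delimited text with a `# n_body,n_heart` header line."""
    A = np.asarray(A, dtype=float)
    with open(path, "w") as f:
        f.write(f"# {A.shape[0]},{A.shape[1]}\n")
        np.savetxt(f, A, delimiter=",", fmt="%.17g")


def read_transfer_csv(path: str | Path) -> np.ndarray:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#"):
            raise ValueError("missing dimension header")
        n_body, n_heart = (int(v) for v in header[1:].split(","))
        A = np.loadtxt(f, delimiter=",", ndmin=2)
    if A.shape != (n_body, n_heart):
        raise ValueError(f"shape {A.shape} does not match header {(n_body, n_heart)}")
    return A


def write_selection(result: SelectionResult, stem: str | Path) -> None:
    """CSV of per-instant lambdas plus a JSON sidecar with the summary."""
    stem = Path(stem)
    pd.DataFrame({
        "t_index": result.instants,
        "lambda": result.lam_per_instant,
        "status": list(result.diagnostics),
    }).to_csv(stem.with_suffix(".csv"), index=False)
    sidecar = {
        "method": result.method,
        "lam_beat": result.lam_beat,
        "interval": {
            "lam_min": result.interval.lam_min,
            "lam_max": result.interval.lam_max,
            "n_grid": result.interval.n_grid,
        },
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_selection(stem: str | Path):
    """Return ``(per_instant_frame, summary_dict)`` for a saved selection."""
    stem = Path(stem)
    frame = pd.read_csv(stem.with_suffix(".csv"))
    summary = json.loads(stem.with_suffix(".json").read_text())
    return frame, summary


def load_config(path: str | Path) -> DatasetConfig:
    with open(path) as f:
        return DatasetConfig.from_dict(yaml.safe_load(f) or {})


def save_config(config: DatasetConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
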