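"""File I/O: meshes (PLY/OFF), recordings (HDF5, delimited, EDF), results.

HDF5 layout for simulated recordings / solver output mirrors the
in-memory objects: datasets ``/M``, ``/X``, ``/J_true`` (or ``/J_hat``),
scalars ``/fs`` and ``/seed``.  EDF reading is available when ``mne`` is
installed; there is no EDF writer here.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .headmodel import CorticalMesh
from .roi import ROILabeling

__all__ = [
    "save_mesh", "load_mesh", "save_recording_h5", "load_recording_h5",
    "save_trials_h5", "load_trials_h5", "save_labeling", "load_delimited",
    "load_recording", "save_solution_h5",
]


def save_mesh(mesh: CorticalMesh, path: str | Path) -> None:
    """Write a mesh as PLY or OFF (by extension)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def load_mesh(path: str | Path) -> CorticalMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    verts = np.asarray(tm.vertices, dtype=float)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return CorticalMesh(vertices=verts, faces=np.asarray(tm.faces, np.int64),
                        normals=normals)


def save_recording_h5(path, X, fs, M=None, J_true=None, seed=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=np.asarray(X))
        f.create_dataset("fs", data=float(fs))
        if M is not None:
            f.create_dataset("M", data=np.asarray(M))
        if J_true is not None:
            f.create_dataset("J_true", data=np.asarray(J_true))
        if seed is not None:
            f.create_dataset("seed", data=int(seed))


def load_recording_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for k in ("X", "M", "J_true", "J_hat"):
            if k in f:
                out[k] = f[k][()]
        out["fs"] = float(f["fs"][()]) if "fs" in f else None
        out["seed"] = int(f["seed"][()]) if "seed" in f else None
    return out


def save_solution_h5(path, solution) -> None:
    """Persist an inverse solution (J_hat, method, hyperparameters, trace)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("J_hat", data=solution.J_hat)
        f.attrs["method"] = solution.method
        if solution.hyper is not None:
            f.create_dataset("lambda_p", data=solution.hyper.lambda_p)
            f.create_dataset("pruned", data=solution.hyper.pruned)
            f.attrs["lambda_eps"] = solution.hyper.lambda_eps
        if solution.objective_trace is not None:
            f.create_dataset("trace", data=solution.objective_trace)
        if solution.regularizer is not None:
            f.attrs["regularizer"] = solution.regularizer


def save_trials_h5(path, trials, fs, ratings=None, seed=None) -> None:
    """Write a trial set as /trials (N, C, T) plus /fs, /ratings, /seed."""
    arr = np.asarray(trials)
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=arr)
        f.create_dataset("fs", data=float(fs))
        if ratings is not None:
            f.create_dataset("ratings", data=np.asarray(ratings))
        if seed is not None:
            f.create_dataset("seed", data=int(seed))


def load_trials_h5(path) -> dict:
    with h5py.File(path, "r") as f:
        out = {"trials": list(f["trials"][()]), "fs": float(f["fs"][()])}
        if "ratings" in f:
            out["ratings"] = f["ratings"][()]
        if "seed" in f:
            out["seed"] = int(f["seed"][()])
    return out


def save_labeling(labeling: ROILabeling, csv_path=None, json_path=None) -> None:
    """Labeling to delimited text (dipole_index,label) and a JSON summary."""
    if csv_path is not None:
        pd.DataFrame({
            "dipole_index": np.arange(labeling.iota.size),
            "label": labeling.iota,
        }).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps({
            "centers": [int(c) for c in labeling.centers],
            "rho": labeling.rho,
            "threshold_frac": labeling.threshold_frac,
            "n_roi": labeling.n_rois,
        }, indent=2))


def load_delimited(path, delimiter=",") -> np.ndarray:
    """Load a channels-by-time matrix from delimited text."""
    try:
        return np.loadtxt(path, delimiter=delimiter)
    except ValueError as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc


def _load_edf(path) -> tuple[np.ndarray, float, list[str]]:
    try:
        import mne
    except ImportError as exc:   # pragma: no cover - depends on environment
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


def load_recording(path, fmt: str | None = None):
    """Load a recording from EDF, HDF5 or delimited text.

    Returns a dict with at least ``X`` (channels x time) and ``fs``
    (None when the format carries no rate).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        X, fs, labels = _load_edf(path)
        out = {"X": X, "fs": fs, "labels": labels}
    elif fmt in ("h5", "hdf5"):
        out = load_recording_h5(path)
    elif fmt in ("csv", "txt", "tsv"):
        out = {"X": load_delimited(path, "\t" if fmt == "tsv" else ","), "fs": None}
    else:
        raise ValueError(f"unknown recording format: {fmt}")
    X = np.asarray(out["X"])
    if not np.all(np.isfinite(X)):
        raise ValueError(f"non-finite samples in {path}")
    return out
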