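"""Reading and writing datasets, window sets and feature matrices.

Disk layout for a dataset directory::

    manifest.json            top-level list of recordings + generator metadata
    rec_00000.csv            one recording, rows = channels (mV)
    rec_00000.json           sidecar: subject, motion, condition, trial, fs

Window sets and feature matrices are stored in single HDF5 containers / CSV
tables respectively.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import EmgRecording

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
    "save_windows_hdf5",
    "load_windows_hdf5",
    "save_features_csv",
    "load_features_csv",
    "save_features_hdf5",
    "load_features_hdf5",
    "load_external_dataset",
]

_CSV_FMT = "%.10e"


def _sidecar(rec: EmgRecording) -> dict:
    cv = rec.condition_value
    if isinstance(cv, (np.integer,)):
        cv = int(cv)
    elif isinstance(cv, (np.floating,)):
        cv = float(cv)
    return {
        "subject_id": int(rec.subject_id),
        "motion_label": str(rec.motion_label),
        "condition_kind": str(rec.condition_kind),
        "condition_value": cv,
        "trial_index": int(rec.trial_index),
        "fs": float(rec.fs),
    }


def save_dataset(recordings: list[EmgRecording], directory) -> Path:
    """Write one CSV + JSON sidecar per recording plus a manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        stem = f"rec_{i:05d}"
        np.savetxt(directory / f"{stem}.csv", rec.data, fmt=_CSV_FMT, delimiter=",")
        meta = _sidecar(rec)
        (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        entries.append({"stem": stem, **meta})
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"n_recordings": len(entries), "recordings": entries},
                                   indent=1, sort_keys=True))
    return manifest


def load_dataset(directory) -> list[EmgRecording]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    recordings = []
    for entry in manifest["recordings"]:
        data = np.loadtxt(directory / f"{entry['stem']}.csv", delimiter=",", ndmin=2)
        recordings.append(
            EmgRecording(
                data=data,
                fs=entry["fs"],
                subject_id=entry["subject_id"],
                motion_label=entry["motion_label"],
                condition_kind=entry["condition_kind"],
                condition_value=entry["condition_value"],
                trial_index=entry["trial_index"],
            )
        )
    return recordings


def save_dataset_hdf5(recordings: list[EmgRecording], path) -> Path:
    """Single-file HDF5 container mirroring the CSV+JSON layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(recordings):
            g = f.create_group(f"rec_{i:05d}")
            g.create_dataset("data", data=rec.data)
            for k, v in _sidecar(rec).items():
                g.attrs[k] = v
    return path


def load_dataset_hdf5(path) -> list[EmgRecording]:
    recordings = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            attrs = dict(g.attrs)
            recordings.append(
                EmgRecording(
                    data=g["data"][()],
                    fs=float(attrs["fs"]),
                    subject_id=int(attrs["subject_id"]),
                    motion_label=str(attrs["motion_label"]),
                    condition_kind=str(attrs["condition_kind"]),
                    condition_value=attrs["condition_value"],
                    trial_index=int(attrs["trial_index"]),
                )
            )
    return recordings


def save_windows_hdf5(windows, path) -> Path:
    from .preprocess import WindowSet  # local import to avoid a cycle

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=windows.windows)
        f.create_dataset("motion_label",
                         data=np.asarray(windows.motion_label, dtype="S"))
        f.create_dataset("condition_value",
                         data=np.asarray([str(v) for v in windows.condition_value], dtype="S"))
        f.create_dataset("condition_value_repr",
                         data=np.asarray([repr(v) for v in windows.condition_value], dtype="S"))
        f.create_dataset("trial_index", data=np.asarray(windows.trial_index, dtype=int))
        f.create_dataset("subject_id", data=np.asarray(windows.subject_id, dtype=int))
        f.attrs["window_ms"] = windows.window_ms
        f.attrs["increment_ms"] = windows.increment_ms
        f.attrs["fs"] = windows.fs
    return path


def _parse_condition(raw: str):
    try:
        v = float(raw)
        return int(v) if v == int(v) and "." not in raw else v
    except ValueError:
        return raw


def load_windows_hdf5(path):
    from .preprocess import WindowSet

    with h5py.File(path, "r") as f:
        cond = [_parse_condition(s.decode()) for s in f["condition_value"][()]]
        return WindowSet(
            windows=f["windows"][()],
            window_ms=float(f.attrs["window_ms"]),
            increment_ms=float(f.attrs["increment_ms"]),
            fs=float(f.attrs["fs"]),
            motion_label=np.asarray([s.decode() for s in f["motion_label"][()]]),
            condition_value=np.asarray(cond, dtype=object),
            trial_index=f["trial_index"][()],
            subject_id=f["subject_id"][()],
        )


def save_features_csv(features, path) -> Path:
    """CSV with header ``subject,motion,condition,trial,FEAT[ch],...``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(features.values, columns=features.feature_names)
    df.insert(0, "trial", features.trial_index)
    df.insert(0, "condition", features.condition_value)
    df.insert(0, "motion", features.motion_label)
    df.insert(0, "subject", features.subject_id)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def save_features_hdf5(features, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=features.values)
        f.create_dataset("feature_names", data=np.asarray(features.feature_names, dtype="S"))
        f.create_dataset("subject_id", data=np.asarray(features.subject_id, dtype=int))
        f.create_dataset("motion_label", data=np.asarray(features.motion_label, dtype="S"))
        f.create_dataset(
            "condition_value",
            data=np.asarray([str(v) for v in features.condition_value], dtype="S"),
        )
        f.create_dataset("trial_index", data=np.asarray(features.trial_index, dtype=int))
    return path


def load_features_hdf5(path):
    from .features import FeatureMatrix

    with h5py.File(path, "r") as f:
        cond = [_parse_condition(s.decode()) for s in f["condition_value"][()]]
        return FeatureMatrix(
            values=f["values"][()],
            feature_names=[s.decode() for s in f["feature_names"][()]],
            subject_id=f["subject_id"][()],
            motion_label=np.asarray([s.decode() for s in f["motion_label"][()]]),
            condition_value=np.asarray(cond, dtype=object),
            trial_index=f["trial_index"][()],
        )


def load_external_dataset(name: str, directory=None):
    """Interface stub for the published multi-condition EMG corpora (five limb
    position, 16 limb position, forearm orientation, MVC-level and subjective
    intensity-level collections).  These have no public accessions; plug in a
    local copy by converting it to this package's CSV + JSON sidecar layout
    and calling :func:`load_dataset`."""
    raise NotImplementedError(
        f"no public accession for dataset {name!r}: convert a local copy to the "
        "CSV+JSON layout (see save_dataset) and use load_dataset instead"
    )


def load_features_csv(path):
    from .features import FeatureMatrix

    df = pd.read_csv(path)
    meta_cols = ["subject", "motion", "condition", "trial"]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(dtype=float),
        feature_names=list(feat_cols),
        subject_id=df["subject"].to_numpy(dtype=int),
        motion_label=df["motion"].to_numpy(dtype=str),
        condition_value=df["condition"].to_numpy(),
        trial_index=df["trial"].to_numpy(dtype=int),
    )
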