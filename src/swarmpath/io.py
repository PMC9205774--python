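"""Checkpoint archives, feature stores and manifests.

Checkpoints are single-file ``.npz`` archives holding the flat parameter
vector, a shape manifest, and a JSON metadata block (hyperparameters, data
hashes, provenance). Tile features live in an HDF5 store with one dataset
per patient (rows = tiles, columns = feature dimensions, layout version
recorded as a root attribute) plus a JSON sidecar describing the backbone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .classifier import ModelParams, PatientBag

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "write_feature_store",
    "read_feature_store",
    "write_manifest",
    "read_manifest",
]

FEATURE_LAYOUT_VERSION = "1"


def save_checkpoint(path: str | Path, model: ModelParams, meta: dict | None = None) -> None:
    shapes = [list(w.shape) for w in model.weights]
    np.savez(
        path,
        flat=model.flatten(),
        shapes=json.dumps(shapes),
        meta=json.dumps(meta or {}, default=str, sort_keys=True),
    )


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    with np.load(path, allow_pickle=False) as z:
        flat = z["flat"]
        shapes = json.loads(str(z["shapes"]))
        meta = json.loads(str(z["meta"]))
    weights = [np.zeros(s) for s in shapes]
    biases = [np.zeros(s[1]) for s in shapes]
    template = ModelParams(weights, biases)
    return template.unflatten(flat), meta


def write_feature_store(
    path: str | Path, bags: Sequence[PatientBag], sidecar: dict | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = FEATURE_LAYOUT_VERSION
        for bag in bags:
            ds = f.create_dataset(bag.patient_id, data=bag.features)
            ds.attrs["cohort_id"] = bag.cohort_id
            ds.attrs["label"] = bag.label
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_feature_store(path: str | Path) -> list[PatientBag]:
    bags = []
    with h5py.File(path, "r") as f:
        for pid in sorted(f.keys()):
            ds = f[pid]
            bags.append(
                PatientBag(pid, str(ds.attrs["cohort_id"]), int(ds.attrs["label"]), ds[...])
            )
    return bags


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
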