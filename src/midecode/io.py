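"""HDF5 array-container persistence for trial sets, images and checkpoints."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import CLASS_NAMES, TrialSet

__all__ = [
    "save_trialset",
    "load_trialset",
    "save_images",
    "load_images",
    "write_event_manifest",
    "save_checkpoint",
    "load_checkpoint",
]


def save_trialset(path: str | Path, trials: TrialSet, images: np.ndarray | None = None) -> None:
    """Datasets: signals (n,3,500), labels (n), run (n), domain_id (n); attrs
    fs, subject_id, session_id; optional images (n,90,90)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=trials.trials)
        f.create_dataset("labels", data=trials.labels)
        f.create_dataset("domain_id", data=trials.domain_ids)
        if trials.runs is not None:
            f.create_dataset("run", data=trials.runs)
        if images is not None:
            f.create_dataset("images", data=np.asarray(images))
        f.attrs["fs"] = trials.fs
        f.attrs["subject_id"] = int(trials.meta.get("subject_id", 0))
        f.attrs["session_id"] = int(trials.meta.get("session_id", 0))


def load_trialset(path: str | Path) -> TrialSet:
    with h5py.File(path, "r") as f:
        return TrialSet(
            trials=f["signals"][...],
            labels=f["labels"][...],
            domain_ids=f["domain_id"][...],
            runs=f["run"][...] if "run" in f else None,
            fs=float(f.attrs.get("fs", 250.0)),
            meta={
                "subject_id": int(f.attrs.get("subject_id", 0)),
                "session_id": int(f.attrs.get("session_id", 0)),
            },
        )


def save_images(path: str | Path, images: np.ndarray) -> None:
    with h5py.File(path, "a") as f:
        if "images" in f:
            del f["images"]
        f.create_dataset("images", data=np.asarray(images))


def load_images(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        if "images" not in f:
            raise KeyError(f"no 'images' dataset in {path}; run featurize first")
        return f["images"][...]


def write_event_manifest(path: str | Path, trials: TrialSet) -> None:
    """CSV manifest: trial index, run, class index/name, domain id."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "run", "label", "class_name", "domain_id"])
        for k in range(len(trials)):
            w.writerow([
                k,
                int(trials.runs[k]) if trials.runs is not None else -1,
                int(trials.labels[k]),
                CLASS_NAMES[trials.labels[k]],
                int(trials.domain_ids[k]),
            ])


# ------------------------------------------------------------------ checkpoints
def _named_tensors(model) -> dict[str, np.ndarray]:
    out = {}
    for i, p in enumerate(model.parameters()):
        out[f"param_{i:03d}"] = p.data
    # batch-norm running statistics are state, not parameters
    for j, layer in enumerate((model.cnn.c1, model.cnn.c2)):
        if layer.bn is not None:
            out[f"bn_{j}_running_mean"] = layer.bn.running_mean
            out[f"bn_{j}_running_var"] = layer.bn.running_var
    return out


def save_checkpoint(path: str | Path, model, config: dict | None = None) -> None:
    """Single HDF5 file with every parameter array plus a JSON manifest attr
    (names, shapes, config)."""
    named = _named_tensors(model)
    manifest = {
        "arrays": {k: list(v.shape) for k, v in named.items()},
        "n_domains": model.n_domains,
        "hidden_size": model.bilstm.hidden_size,
        "ssae_dims": list(model.ssae.hidden_dims),
        "merge_mode": model.bilstm.merge_mode,
        "input_scale": model.input_scale,
        "batch_norm": model.cnn.c1.bn is not None,
        "config": config or {},
    }
    with h5py.File(path, "w") as f:
        for k, v in named.items():
            f.create_dataset(k, data=v)
        f.attrs["manifest"] = json.dumps(manifest)


def load_checkpoint(path: str | Path):
    from .networks import FusionModel

    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        model = FusionModel(
            n_domains=manifest["n_domains"],
            hidden_size=manifest["hidden_size"],
            ssae_dims=tuple(manifest["ssae_dims"]),
            merge_mode=manifest["merge_mode"],
            batch_norm=manifest["batch_norm"],
            input_scale=manifest["input_scale"],
        )
        for i, p in enumerate(model.parameters()):
            p.data = f[f"param_{i:03d}"][...]
        for j, layer in enumerate((model.cnn.c1, model.cnn.c2)):
            if layer.bn is not None:
                layer.bn.running_mean = f[f"bn_{j}_running_mean"][...]
                layer.bn.running_var = f[f"bn_{j}_running_var"][...]
    return model, manifest
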