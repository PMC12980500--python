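"""Checkpoints and attribution-map stores.

A model checkpoint is a single ``.npz`` parameter archive plus a JSON sidecar
holding the estimator configuration, seeds and validation metrics. A map
store is one float32 array file per (model tag, method) with a JSON config
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import ECGNet, ECGResNetClassifier, ModelConfig


def save_model(clf: ECGResNetClassifier, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = clf.net_.state()
    np.savez(path.with_suffix(".npz"), **{k.replace("/", "_"): v for k, v in state.items()})
    sidecar = {
        "params": clf.get_params(),
        "init_seed": clf.net_.init_seed,
        "threshold": clf.threshold_,
        "best_val_auroc": clf.best_val_auroc_,
        "history": clf.history_,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> ECGResNetClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    clf = ECGResNetClassifier(**sidecar["params"])
    net = ECGNet(clf._model_config(), init_seed=sidecar["init_seed"])
    with np.load(path.with_suffix(".npz")) as archive:
        state = {k: archive[k] for k in archive.files}
    net.load_state(state)
    clf.net_ = net
    clf.threshold_ = sidecar["threshold"]
    clf.best_val_auroc_ = sidecar["best_val_auroc"]
    clf.history_ = sidecar["history"]
    clf.classes_ = np.array([0, 1])
    return clf


def save_maps(values: np.ndarray, model_tag: str, method: str, directory,
              config: dict | None = None) -> Path:
    """Store an [N, 8, L] float32 stack of maps with its JSON sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    base = d / f"{model_tag}__{method}"
    np.save(base.with_suffix(".npy"), np.asarray(values, np.float32))
    base.with_suffix(".json").write_text(json.dumps(
        {"model_tag": model_tag, "method": method, "config": config or {}}, indent=1))
    return base.with_suffix(".npy")


def load_maps(model_tag: str, method: str, directory):
    base = Path(directory) / f"{model_tag}__{method}"
    values = np.load(base.with_suffix(".npy")).astype(float)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    return values, sidecar
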