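"""Shared fixtures: toy networks and one trained desk-scale AF model."""

from __future__ import annotations

import numpy as np
import pytest

import ecgxai as ex
from ecgxai import nn
from ecgxai.model import ScalarNet


class FlatLinear(nn.Layer):
    """score = sum(w * x) over all leads/samples — an exactly linear model."""

    deeplift_safe = True

    def __init__(self, w):
        self.w = np.asarray(w, float)  # [8, L]

    def forward(self, x, train=False):
        return (x * self.w[None]).sum(axis=(1, 2))[:, None]

    def backward(self, g, mode="grad", need_param_grads=False):
        return g[:, 0][:, None, None] * self.w[None]


def linear_model(w) -> ScalarNet:
    return ScalarNet(nn.Sequential([FlatLinear(w)]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def tiny_net():
    """Small untrained residual net (4 conv, 4 base channels, L=64)."""
    cfg = ex.ModelConfig(n_conv_layers=4, base_channels=4, input_length=64,
                         dropout_rate=0.0)
    return ex.build_model(cfg, init_seed=3)


@pytest.fixture(scope="session")
def tiny_input(rng):
    return rng.normal(0.0, 1.0, (8, 64))


@pytest.fixture(scope="session")
def af_setup():
    """Trained atrial-fibrillation desk model + patient-disjoint eval records.

    The AF class plants a local feature (absent P wave), learnable by the
    fast 4-conv profile; larger receptive fields are only needed for the
    timing classes, which the separability gate covers separately.
    """
    ds = ex.generate_dataset(300, 3.0, seed=7, noise_sd=0.03)
    train, val, test = ex.split_by_patient(ds, 40, 40, seed=8)
    cls = "atrial_fibrillation"
    clf = ex.ECGResNetClassifier(
        n_conv_layers=4, base_channels=8, input_length=600, epochs=30,
        patience=8, batch_size=32, lr=1.5e-3, stop_auroc=0.999, random_state=0)
    clf.fit(train.signals(), train.labels_for(cls),
            val.signals(), val.labels_for(cls))

    y = test.labels_for(cls)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    idx = np.sort(np.concatenate([pos[:12], neg[:12]]))
    records = [test.records[i].signal for i in idx]
    masks = [test.records[i].relevance_mask for i in idx]
    wide_idx = np.sort(np.concatenate([pos, neg[:36]]))
    return {"clf": clf, "train": train, "val": val, "test": test,
            "class": cls, "records": records, "labels": y[idx], "masks": masks,
            "record_indices": idx,
            "wide_records": [test.records[i].signal for i in wide_idx],
            "wide_labels": y[wide_idx],
            "region": ex.synth.class_discriminative_region(cls)}
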