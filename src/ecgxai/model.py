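"""1D residual convolutional ECG classifiers.

The task model mirrors the architecture family used for median-beat ECG
classification: stacks of residual blocks of two same-padded 1D convolutions
(kernel 7 by default), each convolution followed by batch normalization,
dropout and ReLU, with the channel dimension doubling and the spatial
dimension halving every ``halve_every`` convolutional layers, a global
average pool, and a single sigmoid output unit for binary classification.

`ECGResNetClassifier` is a scikit-learn-style estimator (``fit`` /
``predict_proba`` / ``decision_function``, ``get_params``/``set_params``,
fitted attributes with a trailing underscore) so it composes with sklearn
model selection. The module also exposes the layer enumeration and
progressive output-to-input weight randomization used by the cascading
randomization experiment.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .exceptions import ConfigurationError
from .metrics import auroc as _auroc, youden_threshold


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the 1D ResNet."""

    n_conv_layers: int = 8
    kernel_size: int = 7
    base_channels: int = 16
    halve_every: int = 2
    dropout_rate: float = 0.1
    input_leads: int = 8
    input_length: int = 600

    def block_plan(self):
        """Per-block (in_channels, out_channels, stride, in_len, out_len).

        Raises ConfigurationError (naming the offending depth) if the spatial
        dimension would underflow before the pooling stage.
        """
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd")
        if self.n_conv_layers < 2 or self.n_conv_layers % 2 != 0:
            raise ConfigurationError("n_conv_layers must be a positive even number (blocks of 2)")
        if self.halve_every < 2 or self.halve_every % 2 != 0:
            raise ConfigurationError("halve_every must be a positive even number")
        n_blocks = self.n_conv_layers // 2
        plan = []
        cin, L, h = self.input_leads, self.input_length, 0
        for b in range(n_blocks):
            convs = (2 * b + 1, 2 * b + 2)
            halves = any(c % self.halve_every == 0 for c in convs)
            stride = 2 if halves else 1
            if halves:
                h += 1
            cout = self.base_channels * (2 ** h)
            if stride == 2 and L < 2:
                raise ConfigurationError(
                    f"spatial dimension underflows at conv layer {convs[0]} "
                    f"(block {b + 1}): length {L} cannot be halved further"
                )
            lout = (L + 2 * (self.kernel_size // 2) - self.kernel_size) // stride + 1
            plan.append((cin, cout, stride, L, lout))
            cin, L = cout, lout
        return plan

    def final_channels(self) -> int:
        return self.block_plan()[-1][1]

    def final_length(self) -> int:
        return self.block_plan()[-1][4]


class ScalarNet:
    """Wraps any layer graph with a single pre-sigmoid output unit.

    Provides batched logits, probabilities, input gradients under the three
    backward modes, and parameter state save/load. Attribution methods only
    rely on this interface, so toy networks used in validation can share it.
    """

    def __init__(self, net):
        self.net = net

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, float)
        single = x.ndim == 2
        if single:
            x = x[None]
        z = self.net.forward(x, train=train)[:, 0]
        return z[0] if single else z

    def proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(np.atleast_1d(self.logits(x)))

    def input_gradient(self, x: np.ndarray, mode: str = "grad") -> np.ndarray:
        """d(pre-sigmoid score)/dx for a batch, under a backward mode."""
        x = np.asarray(x, float)
        single = x.ndim == 2
        if single:
            x = x[None]
        self.net.forward(x, train=False)
        g = self.net.backward(np.ones((x.shape[0], 1)), mode=mode)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite input gradient from backward pass")
        return g[0] if single else g

    def state(self) -> dict:
        return {k: v.copy() for k, v in self.net.named_params()}

    def load_state(self, state: dict) -> None:
        for k, v in self.net.named_params():
            v[...] = state[k]

    def clone(self):
        return copy.deepcopy(self)


class ECGNet(ScalarNet):
    """A built network: residual trunk + global average pool + linear head."""

    def __init__(self, cfg: ModelConfig, init_seed: int):
        self.cfg = cfg
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(self.init_seed)
        blocks = []
        for (cin, cout, stride, _, _) in cfg.block_plan():
            main = nn.Sequential([
                nn.Conv1d(cin, cout, cfg.kernel_size, stride=stride, rng=rng),
                nn.BatchNorm1d(cout),
                nn.Dropout(cfg.dropout_rate, rng=np.random.default_rng(rng.integers(2 ** 31))),
                nn.ReLU(),
                nn.Conv1d(cout, cout, cfg.kernel_size, stride=1, rng=rng),
                nn.BatchNorm1d(cout),
                nn.Dropout(cfg.dropout_rate, rng=np.random.default_rng(rng.integers(2 ** 31))),
            ])
            if stride != 1 or cin != cout:
                shortcut = nn.Sequential([
                    nn.Conv1d(cin, cout, 1, stride=stride, rng=rng),
                    nn.BatchNorm1d(cout),
                ])
            else:
                shortcut = None
            blocks.append(nn.ResidualBlock(main, shortcut))
        self.blocks = blocks
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Linear(cfg.final_channels(), 1, rng=rng)
        self.trunk = nn.Sequential(blocks)
        super().__init__(nn.Sequential([self.trunk, self.pool, self.head]))


def build_model(cfg: ModelConfig, init_seed: int) -> ECGNet:
    """Build a seed-initialized network; identical seeds give identical weights."""
    return ECGNet(cfg, init_seed)


@dataclass
class RandomizableLayer:
    """One unit of the output-first randomization walk.

    ``layer`` is the weight-bearing conv/linear layer itself; ``coupled``
    holds modules re-initialized together with it (the batch normalization
    that consumes its output — statistics and affine parameters would
    otherwise leak trained information — and, for a block's leading conv,
    the block's projection shortcut).
    """

    name: str
    layer: object
    coupled: list = field(default_factory=list)


def enumerate_randomizable_layers(model) -> list[RandomizableLayer]:
    """Weight-bearing layers ordered output-first (head, then convs back to input)."""
    net = model.net_ if hasattr(model, "net_") else model
    out = [RandomizableLayer("head", net.head)]
    n_blocks = len(net.blocks)
    for bi in range(n_blocks - 1, -1, -1):
        block = net.blocks[bi]
        conv1, bn1 = block.main.layers[0], block.main.layers[1]
        conv2, bn2 = block.main.layers[4], block.main.layers[5]
        out.append(RandomizableLayer(f"block{bi + 1}.conv2", conv2, [bn2]))
        coupled = [bn1]
        if block.shortcut is not None:
            coupled += list(block.shortcut.layers)
        out.append(RandomizableLayer(f"block{bi + 1}.conv1", conv1, coupled))
    return out


def randomize_top_k_layers(model, k: int, seed: int):
    """Re-initialize the k output-most layers; returns a new model, input untouched."""
    layers = enumerate_randomizable_layers(model)
    if not (0 <= k <= len(layers)):
        raise ValueError(f"k={k} outside [0, {len(layers)}]")
    new = copy.deepcopy(model)
    new_layers = enumerate_randomizable_layers(new)
    rng = np.random.default_rng(int(seed))
    for unit in new_layers[:k]:
        unit.layer.reinitialize(rng)
        for c in unit.coupled:
            c.reinitialize(rng)
    return new


def experiment_grid(classes, n_seeds: int):
    """Cartesian (class, seed) job list, class-major, ascending seed."""
    classes = list(classes)
    if not classes:
        raise ValueError("empty class list")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    return [(c, s) for c in classes for s in range(n_seeds)]


class ECGResNetClassifier(ClassifierMixin, BaseEstimator):
    """Binary 1D-ResNet ECG classifier trained with Adam on cross-entropy.

    Parameters mirror :class:`ModelConfig` plus the training schedule. The
    best-validation-AUROC parameter snapshot is restored after training and
    the decision threshold is set by Youden's J on the validation set.

    Attributes set by :meth:`fit` (trailing underscore): ``net_``,
    ``history_``, ``best_val_auroc_``, ``threshold_``, ``classes_``.
    """

    def __init__(self, n_conv_layers=8, kernel_size=7, base_channels=16,
                 halve_every=2, dropout_rate=0.1, input_length=600,
                 epochs=30, batch_size=64, lr=1e-3, patience=5,
                 val_fraction=0.15, stop_auroc=None, random_state=0):
        self.n_conv_layers = n_conv_layers
        self.kernel_size = kernel_size
        self.base_channels = base_channels
        self.halve_every = halve_every
        self.dropout_rate = dropout_rate
        self.input_length = input_length
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.stop_auroc = stop_auroc  # optional early stop once val AUROC reached
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_conv_layers=self.n_conv_layers, kernel_size=self.kernel_size,
            base_channels=self.base_channels, halve_every=self.halve_every,
            dropout_rate=self.dropout_rate, input_length=self.input_length,
        )

    @staticmethod
    def _validate_X(X):
        X = np.asarray(X, float)
        if X.ndim != 3 or X.shape[1] != 8:
            raise ValueError(f"X must be [n_records, 8 leads, length], got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y, X_val=None, y_val=None, groups=None, val_groups=None):
        X = self._validate_X(X)
        y = np.asarray(y).astype(float).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            n = len(X)
            n_val = max(2, int(round(self.val_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val = self._validate_X(X_val)
            y_val = np.asarray(y_val).astype(float).ravel()
            if groups is not None and val_groups is not None:
                overlap = set(np.asarray(groups).tolist()) & set(np.asarray(val_groups).tolist())
                if overlap:
                    raise ValueError(f"train/validation patients overlap: {sorted(overlap)[:5]}")

        net = build_model(self._model_config(), init_seed=int(rng.integers(2 ** 31)))
        opt = nn.Adam(net.net, lr=self.lr)
        best_state = net.state()
        best_auroc, best_epoch = -np.inf, -1
        history = []
        val_has_two = len(np.unique(y_val)) == 2

        for epoch in range(int(self.epochs)):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                z = net.logits(xb, train=True)
                p = nn.sigmoid(z)
                eps = 1e-12
                losses.append(-np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)))
                nn.zero_grads(net.net)
                net.net.backward(((p - yb) / len(idx))[:, None],
                                 mode="grad", need_param_grads=True)
                opt.step()
            if val_has_two:
                va = _auroc(self._scores(net, X_val), y_val)
            else:
                va = float("nan")
            history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_auroc": va})
            if val_has_two and va > best_auroc:
                best_auroc, best_epoch, best_state = va, epoch, net.state()
            if val_has_two and self.stop_auroc is not None and va >= self.stop_auroc:
                break
            if val_has_two and epoch - best_epoch >= self.patience:
                break

        if self.epochs > 0 and np.isfinite(best_auroc):
            net.load_state(best_state)

        self.net_ = net
        self.history_ = history
        self.best_val_auroc_ = float(best_auroc) if np.isfinite(best_auroc) else float("nan")
        self.classes_ = np.array([0, 1])
        if self.epochs > 0 and val_has_two:
            val_scores = self._scores(net, X_val)
            self.threshold_ = float(youden_threshold(nn.sigmoid(val_scores), y_val))
        else:
            self.threshold_ = 0.5
        return self

    @staticmethod
    def _scores(net: ECGNet, X: np.ndarray, chunk: int = 256) -> np.ndarray:
        out = [net.logits(X[i:i + chunk]) for i in range(0, len(X), chunk)]
        return np.concatenate([np.atleast_1d(o) for o in out])

    def decision_function(self, X):
        X = self._validate_X(X)
        return self._scores(self.net_, X)

    def predict_proba(self, X):
        p = nn.sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold_).astype(int)
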