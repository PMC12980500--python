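"""Minimal NumPy layer framework for 1D convolutional networks.

Implements exactly the layer types the ECG task model needs (1D convolution,
batch normalization, ReLU, dropout, global average pooling, linear, residual
blocks) with hand-coded forward/backward passes. Three backward modes are
supported, because the attribution methods need more than plain gradients:

``grad``
    ordinary vector-Jacobian product (used for training and for the
    gradient-based attribution methods);
``guided``
    guided backpropagation: each ReLU passes gradient only where its forward
    input was positive AND the incoming gradient is positive;
``deeplift``
    multiplier backpropagation under the rescale rule, computed against a
    reference (baseline) forward pass stored by :meth:`Layer.forward_dual`.

All arrays are float64: the attribution axioms (summation-to-delta,
completeness) are checked to 1e-6 and tighter, which single precision cannot
guarantee through a deep network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS_DELTA = 1e-9  # |delta input| below this -> fall back to gradient rule


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    """Base class. Subclasses cache what their backward pass needs."""

    def params(self) -> dict:
        return {}

    def named_params(self, prefix=""):
        for k, v in self.params().items():
            yield f"{prefix}{k}", v

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def forward_dual(self, x, b):
        """Eval-mode forward on input and baseline jointly (DeepLift)."""
        self._dual_in = (x, b)
        out = self.forward(x, train=False), self.forward(b, train=False)
        self._dual_out = out
        return out

    def backward(self, g, mode="grad", need_param_grads=False):
        raise NotImplementedError


class Conv1d(Layer):
    """'Same'-padded 1D convolution, odd kernel, optional stride."""

    def __init__(self, cin, cout, kernel_size, stride=1, rng=None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel_size, stride
        self.pad = kernel_size // 2
        self.W = he_init(rng, (cout, cin, kernel_size), cin * kernel_size)
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def reinitialize(self, rng):
        self.W[...] = he_init(rng, self.W.shape, self.cin * self.k)
        self.b[...] = 0.0

    def out_length(self, L):
        return (L + 2 * self.pad - self.k) // self.stride + 1

    def _cols(self, x):
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.stride, :]
        return np.ascontiguousarray(cols)  # [N, Cin, Lout, K]

    def forward(self, x, train=False):
        cols = self._cols(x)
        self._cache = (x.shape, cols)
        n, _, lout, _ = cols.shape
        out = np.matmul(
            self.W.reshape(self.cout, -1),
            cols.transpose(0, 2, 1, 3).reshape(n, lout, -1).transpose(0, 2, 1),
        )
        return out + self.b[None, :, None]

    def backward(self, g, mode="grad", need_param_grads=False):
        x_shape, cols = self._cache
        n, cin, lout, k = cols.shape
        if need_param_grads:
            flat = cols.transpose(0, 2, 1, 3).reshape(n * lout, cin * k)
            gflat = g.transpose(0, 2, 1).reshape(n * lout, self.cout)
            self.gW += (gflat.T @ flat).reshape(self.W.shape)
            self.gb += g.sum(axis=(0, 2))
        dcols = np.matmul(
            self.W.reshape(self.cout, -1).T, g
        )  # [N, Cin*K, Lout]
        dcols = dcols.reshape(n, cin, k, lout)
        L = x_shape[2]
        dxp = np.zeros((n, cin, L + 2 * self.pad))
        idx = self.stride * np.arange(lout)
        for j in range(k):
            # indices idx+j are unique for fixed j, so buffered += is exact
            dxp[:, :, idx + j] += dcols[:, :, j, :]
        return dxp[:, :, self.pad : self.pad + L]


class BatchNorm1d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.c = c
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def reinitialize(self, rng):  # fresh affine + statistics
        self.gamma[...] = 1.0
        self.beta[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, g, mode="grad", need_param_grads=False):
        xhat, inv, was_train, shape = self._cache
        if need_param_grads:
            self.ggamma += (g * xhat).sum(axis=(0, 2))
            self.gbeta += g.sum(axis=(0, 2))
        gam_inv = (self.gamma * inv)[None, :, None]
        if not was_train:
            # inference-mode BN is a per-channel affine map
            return g * gam_inv
        m = shape[0] * shape[2]
        gxhat = g * self.gamma[None, :, None]
        return (inv[None, :, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )


class ReLU(Layer):
    def forward(self, x, train=False):
        self._in = x
        return np.maximum(x, 0.0)

    def backward(self, g, mode="grad", need_param_grads=False):
        if mode == "guided":
            return g * (self._in > 0) * (g > 0)
        if mode == "deeplift":
            xin, bin_ = self._dual_in
            xout, bout = self._dual_out
            dx = xin - bin_
            ratio = np.where(
                np.abs(dx) > _EPS_DELTA,
                (xout - bout) / np.where(np.abs(dx) > _EPS_DELTA, dx, 1.0),
                (xin > 0).astype(float),
            )
            return g * ratio
        return g * (self._in > 0)

    def forward_dual(self, x, b):
        self._dual_in = (x, b)
        out = np.maximum(x, 0.0), np.maximum(b, 0.0)
        self._dual_out = out
        self._in = x
        return out


class Dropout(Layer):
    """Inverted dropout; identity in eval mode (attribution is always eval)."""

    def __init__(self, p, rng=None):
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x, train=False):
        if train and self.p > 0:
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, g, mode="grad", need_param_grads=False):
        if self._mask is not None:
            return g * self._mask
        return g


class GlobalAvgPool(Layer):
    """[N, C, L] -> [N, C]."""

    def forward(self, x, train=False):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g, mode="grad", need_param_grads=False):
        return np.repeat(g[:, :, None], self._L, axis=2) / self._L


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.W = he_init(rng, (cout, cin), cin)
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def reinitialize(self, rng):
        self.W[...] = he_init(rng, self.W.shape, self.cin)
        self.b[...] = 0.0

    def forward(self, x, train=False):
        self._in = x
        return x @ self.W.T + self.b

    def backward(self, g, mode="grad", need_param_grads=False):
        if need_param_grads:
            self.gW += g.T @ self._in
            self.gb += g.sum(axis=0)
        return g @ self.W


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def named_params(self, prefix=""):
        for i, l in enumerate(self.layers):
            yield from l.named_params(f"{prefix}{i}.")

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def forward_dual(self, x, b):
        for l in self.layers:
            x, b = l.forward_dual(x, b)
        return x, b

    def backward(self, g, mode="grad", need_param_grads=False):
        for l in reversed(self.layers):
            g = l.backward(g, mode=mode, need_param_grads=need_param_grads)
        return g


class ResidualBlock(Layer):
    """out = ReLU(main(x) + shortcut(x)); shortcut is identity or projection."""

    def __init__(self, main: Sequential, shortcut: Sequential | None):
        self.main = main
        self.shortcut = shortcut
        self.post = ReLU()

    def named_params(self, prefix=""):
        yield from self.main.named_params(f"{prefix}main.")
        if self.shortcut is not None:
            yield from self.shortcut.named_params(f"{prefix}shortcut.")

    def forward(self, x, train=False):
        m = self.main.forward(x, train=train)
        s = self.shortcut.forward(x, train=train) if self.shortcut is not None else x
        return self.post.forward(m + s, train=train)

    def forward_dual(self, x, b):
        mx, mb = self.main.forward_dual(x, b)
        if self.shortcut is not None:
            sx, sb = self.shortcut.forward_dual(x, b)
        else:
            sx, sb = x, b
        return self.post.forward_dual(mx + sx, mb + sb)

    def backward(self, g, mode="grad", need_param_grads=False):
        g = self.post.backward(g, mode=mode, need_param_grads=need_param_grads)
        gm = self.main.backward(g, mode=mode, need_param_grads=need_param_grads)
        if self.shortcut is not None:
            gs = self.shortcut.backward(g, mode=mode, need_param_grads=need_param_grads)
        else:
            gs = g
        return gm + gs


def iter_layers(layer):
    """Depth-first iteration over primitive layers."""
    if isinstance(layer, Sequential):
        for l in layer.layers:
            yield from iter_layers(l)
    elif isinstance(layer, ResidualBlock):
        yield from iter_layers(layer.main)
        if layer.shortcut is not None:
            yield from iter_layers(layer.shortcut)
        yield layer.post
    else:
        yield layer


def collect_trainable(layer):
    """(layer, attr) pairs for every trainable tensor, input->output order."""
    out = []
    for l in iter_layers(layer):
        if isinstance(l, Conv1d) or isinstance(l, Linear):
            out.append((l, "W"))
            out.append((l, "b"))
        elif isinstance(l, BatchNorm1d):
            out.append((l, "gamma"))
            out.append((l, "beta"))
    return out


def zero_grads(layer):
    for l in iter_layers(layer):
        for a in ("gW", "gb", "ggamma", "gbeta"):
            if hasattr(l, a):
                getattr(l, a)[...] = 0.0


class Adam:
    """Adam on the trainable tensors of a network."""

    def __init__(self, net, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = collect_trainable(net)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, a)) for l, a in self.pairs]
        self.v = [np.zeros_like(getattr(l, a)) for l, a in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (l, a) in enumerate(self.pairs):
            g = getattr(l, "g" + a)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            getattr(l, a)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
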