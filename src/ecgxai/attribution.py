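"""The 12 attribution methods, implemented from first principles.

Every method maps a model and an input signal [8 leads x L samples] to a
relevance map of the same shape. The attribution target is the pre-sigmoid
score (the logit): gradients of the probability vanish at saturated outputs,
which would flatten maps for confidently classified records.

Gradient-flavoured methods (Saliency, Gradient*Input, Integrated Gradients,
SmoothGrad and the SHAP expectation variants) ride on the network's ordinary
backward pass; Guided Backpropagation and DeepLift use the dedicated backward
modes of :mod:`ecgxai.nn`; GradCAM reads activations and gradients at a
convolutional tap layer; Shapley sampling treats contiguous time segments
(jointly across leads) as players in a cooperative game and estimates their
Shapley values by permutation sampling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .exceptions import CapabilityError, ConfigurationError

METHODS = (
    "saliency", "smoothgrad", "gradient_input", "guided_backprop", "gradcam",
    "guided_gradcam", "shapley_sampling", "deeplift", "integrated_gradients",
    "ig_smoothgrad", "gradientshap", "deepliftshap",
)

_SUPPORTED_LAYERS = (nn.Conv1d, nn.BatchNorm1d, nn.ReLU, nn.Dropout,
                     nn.GlobalAvgPool, nn.Linear)


@dataclass
class MethodConfig:
    """Hyperparameters shared by the method dispatch."""

    ig_steps: int = 64
    sg_samples: int = 32
    sg_noise: float = 0.1          # fraction of the input's value range
    shapley_segments: int = 32
    shapley_samples: int = 256
    shap_baselines: int = 16
    gradcam_tap: int = -1          # block index of the tap layer
    seed: int = 0

    def __post_init__(self):
        for k in ("ig_steps", "sg_samples", "shapley_segments",
                  "shapley_samples", "shap_baselines"):
            if getattr(self, k) < 1:
                raise ConfigurationError(f"{k} must be >= 1")
        if self.sg_noise < 0:
            raise ConfigurationError("sg_noise must be >= 0")

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class AttributionMap:
    values: np.ndarray            # [8, L]
    method_id: str
    target: str = ""
    model_tag: str = ""
    config_hash: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError(f"{self.method_id}: non-finite attribution values")


def _net(model):
    return model.net_ if hasattr(model, "net_") else model


def _check_supported(net):
    # layers outside the built-in set may declare rescale-rule support by
    # setting a `deeplift_safe` attribute (exactly linear operations qualify)
    for layer in nn.iter_layers(net.net):
        if not isinstance(layer, _SUPPORTED_LAYERS) and not getattr(
                layer, "deeplift_safe", False):
            raise CapabilityError(f"unsupported layer type {type(layer).__name__}")


# ---------------------------------------------------------------------------
# gradient family
# ---------------------------------------------------------------------------

def saliency(model, x, target="") -> AttributionMap:
    """|d score / d x|."""
    g = _net(model).input_gradient(np.asarray(x, float))
    return AttributionMap(np.abs(g), "saliency", target)


def gradient_input(model, x, target="") -> AttributionMap:
    """x * d score / d x (signed)."""
    x = np.asarray(x, float)
    g = _net(model).input_gradient(x)
    return AttributionMap(x * g, "gradient_input", target)


def integrated_gradients(model, x, baseline=None, n_steps: int = 64,
                         target="") -> AttributionMap:
    """(x - baseline) * mean gradient along the straight path (midpoint rule).

    As n_steps grows the map's sum converges to score(x) - score(baseline)
    (the completeness axiom).
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    x = np.asarray(x, float)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    if b.shape != x.shape:
        raise ValueError("baseline shape must match input shape")
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    batch = b[None] + alphas[:, None, None] * (x - b)[None]
    grads = _net(model).input_gradient(batch)
    return AttributionMap((x - b) * grads.mean(axis=0), "integrated_gradients", target)


def smoothgrad_wrap(base_method, model, x, target="", n_samples: int = 32,
                    noise_sd: float = 0.1, seed: int = 0, method_id: str | None = None,
                    **base_kwargs) -> AttributionMap:
    """Mean of base-method maps over Gaussian-perturbed copies of the input.

    ``noise_sd`` is a fraction of the input's value range. With zero noise
    the wrapper returns the base map exactly, regardless of n_samples.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    x = np.asarray(x, float)
    name = method_id or f"smoothgrad[{getattr(base_method, '__name__', 'base')}]"
    if noise_sd == 0:
        m = base_method(model, x, target=target, **base_kwargs)
        return AttributionMap(m.values, name, target)
    scale = noise_sd * (x.max() - x.min())
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(x)
    for _ in range(n_samples):
        xp = x + rng.normal(0.0, scale, x.shape)
        acc += base_method(model, xp, target=target, **base_kwargs).values
    return AttributionMap(acc / n_samples, name, target)


def smoothgrad(model, x, target="", n_samples=32, noise_sd=0.1, seed=0) -> AttributionMap:
    return smoothgrad_wrap(saliency, model, x, target=target, n_samples=n_samples,
                           noise_sd=noise_sd, seed=seed, method_id="smoothgrad")


def ig_smoothgrad(model, x, target="", n_samples=32, noise_sd=0.1, seed=0,
                  baseline=None, n_steps=64) -> AttributionMap:
    return smoothgrad_wrap(integrated_gradients, model, x, target=target,
                           n_samples=n_samples, noise_sd=noise_sd, seed=seed,
                           method_id="ig_smoothgrad", baseline=baseline, n_steps=n_steps)


# ---------------------------------------------------------------------------
# reference-based family
# ---------------------------------------------------------------------------

def deeplift_rescale(model, x, baseline=None, target="") -> AttributionMap:
    """DeepLift under the rescale rule.

    Multipliers equal delta-activation / delta-input per unit, chain-composed;
    for networks of linear operations and ReLUs the attributions satisfy
    summation-to-delta exactly (up to float rounding).
    """
    net = _net(model)
    _check_supported(net)
    x = np.asarray(x, float)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    if b.shape != x.shape:
        raise ValueError("baseline shape must match input shape")
    net.net.forward_dual(x[None], b[None])
    m = net.net.backward(np.ones((1, 1)), mode="deeplift")[0]
    return AttributionMap(m * (x - b), "deeplift", target)


def gradientshap(model, x, baselines, target="", n_samples: int = 32,
                 noise_sd: float = 0.0, seed: int = 0) -> AttributionMap:
    """Expectation over random baselines/path positions of (x - b) * grad."""
    baselines = np.asarray(baselines, float)
    if baselines.ndim != 3 or len(baselines) < 1:
        raise ConfigurationError("baselines must be a non-empty [k, 8, L] stack")
    x = np.asarray(x, float)
    rng = np.random.default_rng(seed)
    scale = noise_sd * (x.max() - x.min()) if noise_sd > 0 else 0.0
    idx = rng.integers(0, len(baselines), n_samples)
    alphas = rng.random(n_samples)
    xs = x[None] + (rng.normal(0.0, scale, (n_samples,) + x.shape) if scale > 0 else 0.0)
    b = baselines[idx]
    points = b + alphas[:, None, None] * (xs - b)
    grads = _net(model).input_gradient(points)
    return AttributionMap(((xs - b) * grads).mean(axis=0), "gradientshap", target)


def deepliftshap(model, x, baselines, target="") -> AttributionMap:
    """Mean of DeepLift rescale attributions over a set of baselines."""
    baselines = np.asarray(baselines, float)
    if baselines.ndim != 3 or len(baselines) < 1:
        raise ConfigurationError("baselines must be a non-empty [k, 8, L] stack")
    acc = np.zeros_like(np.asarray(x, float))
    for b in baselines:
        acc += deeplift_rescale(model, x, baseline=b, target=target).values
    return AttributionMap(acc / len(baselines), "deepliftshap", target)


# ---------------------------------------------------------------------------
# Shapley sampling
# ---------------------------------------------------------------------------

def segment_bounds(L: int, n_segments: int):
    """Contiguous, near-equal time segments covering [0, L)."""
    if n_segments > L:
        raise ConfigurationError(f"n_segments={n_segments} exceeds record length {L}")
    edges = np.linspace(0, L, n_segments + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_segments)]


def shapley_sampling(model, x, baseline=None, n_segments: int = 32,
                     n_samples: int = 256, seed: int = 0, target="",
                     per_lead: bool = False) -> AttributionMap:
    """Permutation-sampling Shapley values of contiguous time segments.

    By default all leads move jointly with their segment, keeping the player
    count at n_segments; with ``per_lead=True`` every (lead, segment) pair is
    its own player (8x the players, correspondingly more model evaluations).
    Each player's estimated value is broadcast uniformly to its points. The
    estimator is unbiased; its Monte-Carlo SE shrinks as 1/sqrt(n_samples).
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    x = np.asarray(x, float)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    net = _net(model)
    n_leads, L = x.shape
    bounds = segment_bounds(L, n_segments)
    if per_lead:
        players = [(lead, lo, hi) for lead in range(n_leads) for lo, hi in bounds]
    else:
        players = [(slice(None), lo, hi) for lo, hi in bounds]
    n_players = len(players)
    rng = np.random.default_rng(seed)
    phi = np.zeros(n_players)
    for _ in range(n_samples):
        order = rng.permutation(n_players)
        # batch of n_players+1 coalition inputs: baseline, then cumulative adds
        batch = np.repeat(b[None], n_players + 1, axis=0)
        current = b.copy()
        for i, p in enumerate(order):
            rows, lo, hi = players[p]
            current[rows, lo:hi] = x[rows, lo:hi]
            batch[i + 1] = current
        scores = np.atleast_1d(net.logits(batch))
        phi[order] += np.diff(scores)
    phi /= n_samples
    values = np.zeros_like(x)
    for p, (rows, lo, hi) in enumerate(players):
        values[rows, lo:hi] = phi[p]
    return AttributionMap(values, "shapley_sampling", target)


def exact_shapley_segments(model, x, baseline, n_segments: int) -> np.ndarray:
    """Exhaustive Shapley values over all n! segment orderings (tiny n only)."""
    from itertools import permutations

    x = np.asarray(x, float)
    b = np.asarray(baseline, float)
    net = _net(model)
    bounds = segment_bounds(x.shape[1], n_segments)
    phi = np.zeros(n_segments)
    perms = list(permutations(range(n_segments)))
    for order in perms:
        current = b.copy()
        prev = float(np.atleast_1d(net.logits(current[None]))[0])
        for seg in order:
            lo, hi = bounds[seg]
            current[:, lo:hi] = x[:, lo:hi]
            now = float(np.atleast_1d(net.logits(current[None]))[0])
            phi[seg] += now - prev
            prev = now
    return phi / len(perms)


# ---------------------------------------------------------------------------
# activation family
# ---------------------------------------------------------------------------

def guided_backprop(model, x, target="") -> AttributionMap:
    """Backward pass where ReLUs pass gradient only if input > 0 and grad > 0."""
    g = _net(model).input_gradient(np.asarray(x, float), mode="guided")
    return AttributionMap(g, "guided_backprop", target)


def gradcam(model, x, target="", tap_block: int = -1) -> AttributionMap:
    """Class activation map at a convolutional tap layer.

    Channel weights are time-averaged gradients of the score at the tap;
    the ReLU-clamped weighted activation sum is linearly upsampled to the
    input length and replicated across the 8 lead rows (post-convolution
    channels mix leads, so per-lead resolution is not recoverable).
    """
    net = _net(model)
    n_blocks = len(net.blocks)
    tap = tap_block if tap_block >= 0 else n_blocks + tap_block
    if not (0 <= tap < n_blocks):
        raise ConfigurationError(f"tap_block {tap_block} not found ({n_blocks} blocks)")
    x = np.asarray(x, float)
    a = x[None]
    acts = []
    for blk in net.blocks:
        a = blk.forward(a, train=False)
        acts.append(a)
    z = net.head.forward(net.pool.forward(a, train=False), train=False)
    g = net.head.backward(np.ones((1, 1)))
    g = net.pool.backward(g)
    for blk in reversed(net.blocks[tap + 1:]):
        g = blk.backward(g)
    weights = g.mean(axis=2)                       # [1, C] time-averaged grads
    cam = np.maximum((weights[:, :, None] * acts[tap]).sum(axis=1), 0.0)[0]
    L, Ltap = x.shape[1], cam.shape[0]
    if Ltap == 1:
        up = np.full(L, cam[0])
    else:
        up = np.interp(np.linspace(0, Ltap - 1, L), np.arange(Ltap), cam)
    return AttributionMap(np.repeat(up[None, :], 8, axis=0), "gradcam", target)


def combine_guided_gradcam(gbp_map, gradcam_map) -> AttributionMap:
    """Elementwise product of guided backpropagation and GradCAM maps."""
    a = gbp_map.values if isinstance(gbp_map, AttributionMap) else np.asarray(gbp_map, float)
    b = gradcam_map.values if isinstance(gradcam_map, AttributionMap) else np.asarray(gradcam_map, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return AttributionMap(a * b, "guided_gradcam")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def compute_attribution(method_id: str, model, x, target="", config: MethodConfig | None = None,
                        baselines: np.ndarray | None = None,
                        model_tag: str = "") -> AttributionMap:
    """Run one of the 12 methods under a shared configuration.

    ``baselines`` (a [k, 8, L] stack, e.g. training-set draws) feeds the SHAP
    expectation variants; when omitted, zero baselines are used everywhere.
    """
    if method_id not in METHODS:
        raise ConfigurationError(f"unknown attribution method '{method_id}'")
    cfg = config or MethodConfig()
    x = np.asarray(x, float)
    zeros = np.zeros_like(x)
    if baselines is None:
        baselines = zeros[None].repeat(cfg.shap_baselines, axis=0) if method_id in (
            "gradientshap", "deepliftshap") else None

    if method_id == "saliency":
        m = saliency(model, x, target)
    elif method_id == "smoothgrad":
        m = smoothgrad(model, x, target, cfg.sg_samples, cfg.sg_noise, cfg.seed)
    elif method_id == "gradient_input":
        m = gradient_input(model, x, target)
    elif method_id == "guided_backprop":
        m = guided_backprop(model, x, target)
    elif method_id == "gradcam":
        m = gradcam(model, x, target, tap_block=cfg.gradcam_tap)
    elif method_id == "guided_gradcam":
        m = combine_guided_gradcam(guided_backprop(model, x, target),
                                   gradcam(model, x, target, tap_block=cfg.gradcam_tap))
    elif method_id == "shapley_sampling":
        m = shapley_sampling(model, x, zeros, cfg.shapley_segments,
                             cfg.shapley_samples, cfg.seed, target)
    elif method_id == "deeplift":
        m = deeplift_rescale(model, x, zeros, target)
    elif method_id == "integrated_gradients":
        m = integrated_gradients(model, x, zeros, cfg.ig_steps, target)
    elif method_id == "ig_smoothgrad":
        m = ig_smoothgrad(model, x, target, cfg.sg_samples, cfg.sg_noise,
                          cfg.seed, baseline=zeros, n_steps=cfg.ig_steps)
    elif method_id == "gradientshap":
        m = gradientshap(model, x, baselines, target, cfg.sg_samples,
                         noise_sd=0.0, seed=cfg.seed)
    else:  # deepliftshap
        m = deepliftshap(model, x, baselines, target)
    m.method_id = method_id
    m.target = target
    m.model_tag = model_tag
    m.config_hash = cfg.hash()
    return m
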