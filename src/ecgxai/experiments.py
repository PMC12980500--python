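"""The four attribution evaluations.

1. Inter-method similarity: correlation between maps from different methods
   on the same model and record.
2. Self-consistency: correlation between maps from models retrained with
   different random seeds on the same data.
3. Cascading randomization: correlation of maps to the trained-model maps as
   layers are progressively re-initialized from the output toward the input,
   alongside the randomized model's AUROC.
4. Remove-and-debias perturbation: iteratively replace the top-attributed
   points with linear interpolation of unmasked neighbours times Gaussian
   noise, re-scoring the model after each step.

All experiments share the map-processing conventions of :mod:`ecgxai.maps`:
similarity experiments (1-3) smooth maps with the Savitzky-Golay filter by
default, while the perturbation ranking uses raw absolute attributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .attribution import MethodConfig, compute_attribution
from .maps import rank_points_abs, savgol_smooth, similarity
from .metrics import auroc
from .model import enumerate_randomizable_layers, randomize_top_k_layers


def _maybe_smooth(m, smooth: bool, window: int, polyorder: int):
    return savgol_smooth(m, window, polyorder) if smooth else m


def _attr(method, model, x, cfg, baselines, tag=""):
    return compute_attribution(method, model, x, config=cfg,
                               baselines=baselines, model_tag=tag)


# ---------------------------------------------------------------------------
# Experiment 1: inter-method similarity
# ---------------------------------------------------------------------------

def run_inter_method(model, records, methods, config: MethodConfig | None = None,
                     baselines=None, smooth: bool = True, window: int = 31,
                     polyorder: int = 3, kind: str = "pearson"):
    """All method-pair similarities per record, plus the aggregate matrix.

    Returns (scores, matrix): long-format per-record scores and a symmetric
    mean-correlation DataFrame with unit diagonal, ordered like ``methods``.
    A method failing on a record skips that record's pairs involving it (the
    skip is counted in the scores frame's attrs).
    """
    methods = list(methods)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    cfg = config or MethodConfig()
    rows, skipped = [], 0
    for ri, x in enumerate(records):
        maps = {}
        for m in methods:
            try:
                maps[m] = _maybe_smooth(_attr(m, model, x, cfg, baselines),
                                        smooth, window, polyorder)
            except Exception as e:  # record skipped for this method's pairs
                skipped += 1
                warnings.warn(f"{m} failed on record {ri}: {e}")
        for a, b in combinations([m for m in methods if m in maps], 2):
            s = similarity(maps[a], maps[b], kind)
            rows.append({"record": ri, "method_a": a, "method_b": b,
                         "value": s.value, "degenerate": s.degenerate_flag})
    scores = pd.DataFrame(rows)
    scores.attrs["n_method_failures"] = skipped
    matrix = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    sd = pd.DataFrame(np.zeros((len(methods), len(methods))), index=methods, columns=methods)
    if not scores.empty:
        for (a, b), grp in scores.groupby(["method_a", "method_b"]):
            mu = float(grp["value"].mean())
            s_ = float(grp["value"].std(ddof=1)) if len(grp) > 1 else 0.0
            matrix.loc[a, b] = matrix.loc[b, a] = mu
            sd.loc[a, b] = sd.loc[b, a] = s_
    matrix.attrs["sd"] = sd
    return scores, matrix


# ---------------------------------------------------------------------------
# Experiment 2: self-consistency across seeds
# ---------------------------------------------------------------------------

def run_self_consistency(models_by_seed: dict, records, methods,
                         config: MethodConfig | None = None, baselines=None,
                         smooth: bool = True, window: int = 31, polyorder: int = 3,
                         kind: str = "pearson"):
    """All unordered seed-pair similarities per method per record.

    ``models_by_seed`` maps seed -> trained model (one diagnostic class).
    For s seeds there are s(s-1)/2 pairs per (method, record).
    """
    seeds = sorted(models_by_seed)
    if len(seeds) < 2:
        raise ValueError("need models for at least 2 seeds")
    cfg = config or MethodConfig()
    rows = []
    for ri, x in enumerate(records):
        for m in methods:
            maps = {s: _maybe_smooth(_attr(m, models_by_seed[s], x, cfg, baselines,
                                           tag=f"seed{s}"),
                                     smooth, window, polyorder) for s in seeds}
            for sa, sb in combinations(seeds, 2):
                s_ = similarity(maps[sa], maps[sb], kind)
                rows.append({"record": ri, "method": m, "seed_a": sa, "seed_b": sb,
                             "value": s_.value, "degenerate": s_.degenerate_flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment 3: cascading randomization
# ---------------------------------------------------------------------------

@dataclass
class RandomizationTrajectory:
    steps: list                      # 0..n_layers
    layer_names: list                # name randomized at each step >= 1
    correlation: pd.DataFrame        # long: step, method, mean, sd, n
    model_auroc: list                # AUROC after each step

    def as_frame(self) -> pd.DataFrame:
        df = self.correlation.copy()
        aur = {s: a for s, a in zip(self.steps, self.model_auroc)}
        df["model_auroc"] = df["step"].map(aur)
        return df


def run_cascading_randomization(trained_model, records, labels, methods,
                                seed: int = 0, config: MethodConfig | None = None,
                                baselines=None, smooth: bool = True,
                                window: int = 31, polyorder: int = 3,
                                kind: str = "pearson") -> RandomizationTrajectory:
    """Progressively randomize layers output->input, tracking map correlation.

    At step k the top k layers of the output-first enumeration are freshly
    re-initialized; each method's maps are correlated against its step-0
    (fully trained) maps, and the randomized model's AUROC on ``records``
    is recorded. Step 0 correlations are exactly 1 by construction.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    labels = np.asarray(labels)
    cfg = config or MethodConfig()
    units = enumerate_randomizable_layers(trained_model)
    n_layers = len(units)

    ref_maps = {m: [_maybe_smooth(_attr(m, trained_model, x, cfg, baselines),
                                  smooth, window, polyorder)
                    for x in records] for m in methods}
    rows, aurocs, steps = [], [], list(range(n_layers + 1))
    for k in steps:
        model_k = trained_model if k == 0 else randomize_top_k_layers(trained_model, k, seed)
        net = model_k.net_ if hasattr(model_k, "net_") else model_k
        scores = np.atleast_1d(net.logits(np.stack(records)))
        aurocs.append(auroc(scores, labels))
        for m in methods:
            vals = []
            for ri, x in enumerate(records):
                if k == 0:
                    vals.append(1.0)
                    continue
                mk = _maybe_smooth(_attr(m, model_k, x, cfg, baselines, tag=f"step{k}"),
                                   smooth, window, polyorder)
                vals.append(similarity(ref_maps[m][ri], mk, kind).value)
            rows.append({"step": k, "method": m, "mean": float(np.mean(vals)),
                         "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                         "n": len(vals)})
    return RandomizationTrajectory(steps, [u.name for u in units],
                                   pd.DataFrame(rows), aurocs)


# ---------------------------------------------------------------------------
# Experiment 4: remove-and-debias perturbation
# ---------------------------------------------------------------------------

def perturb_step(signal: np.ndarray, cumulative_mask: np.ndarray, ranking: np.ndarray,
                 step_frac: float, noise_sd: float, rng: np.random.Generator,
                 mode: str = "multiplicative"):
    """Mask the next ceil(step_frac * n_points) top-ranked points and debias them.

    Each newly selected point is replaced by linear interpolation between its
    nearest unmasked neighbours on the same lead (constant extension at the
    boundaries), multiplied by Normal(1, noise_sd) noise — or with additive
    Normal(0, noise_sd) noise in ``additive`` mode. Previously masked points
    keep their imputed values; unmasked points are untouched. Returns the new
    (signal, cumulative_mask); inputs are not modified.
    """
    if not (0 < step_frac <= 1):
        raise ValueError("step_frac must be in (0, 1]")
    n_leads, L = signal.shape
    flat_mask = cumulative_mask.ravel()
    if flat_mask.all():
        raise ValueError("cumulative mask is already full")
    count = math.ceil(step_frac * signal.size)
    fresh = [i for i in ranking if not flat_mask[i]][:count]
    new_mask = cumulative_mask.copy()
    new_mask.ravel()[fresh] = True

    out = signal.copy()
    for lead in range(n_leads):
        sel = new_mask[lead] & ~cumulative_mask[lead]
        if not sel.any():
            continue
        keep = ~new_mask[lead]
        t_sel = np.flatnonzero(sel)
        if keep.any():
            t_keep = np.flatnonzero(keep)
            interp = np.interp(t_sel, t_keep, signal[lead, t_keep])
        else:
            interp = np.zeros(len(t_sel))
        if mode == "multiplicative":
            interp = interp * rng.normal(1.0, noise_sd, len(t_sel))
        elif mode == "additive":
            interp = interp + rng.normal(0.0, noise_sd, len(t_sel))
        else:
            raise ValueError(f"unknown noise mode '{mode}'")
        out[lead, t_sel] = interp
    return out, new_mask


@dataclass
class PerturbationTrajectory:
    steps: list
    cumulative_fraction: list
    auroc_by_method: dict            # method -> list of AUROC per step

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for m, currs in self.auroc_by_method.items():
            for s, f, a in zip(self.steps, self.cumulative_fraction, currs):
                rows.append({"step": s, "cumulative_fraction": f, "method": m,
                             "auroc": a})
        return pd.DataFrame(rows)


def run_perturbation(trained_model, records, labels, methods, n_steps: int = 30,
                     step_frac: float = 0.01, noise_sd: float = 0.25, seed: int = 0,
                     config: MethodConfig | None = None, baselines=None,
                     noise_mode: str = "multiplicative",
                     rankings_override: dict | None = None,
                     recompute_ranking: bool = False) -> PerturbationTrajectory:
    """Iterative top-attribution perturbation with model re-scoring.

    The ranking is computed once per (method, record) from the raw absolute
    attributions of the unperturbed input and held fixed; each of the
    ``n_steps`` steps masks a further ``step_frac`` of all points. AUROC is
    recomputed on the perturbed records after every step. ``rankings_override``
    maps a method name to a list of per-record rankings (used for the oracle
    and random-ranking controls). ``recompute_ranking=True`` switches to the
    sensitivity-analysis mode that re-attributes the perturbed signal before
    every step (n_steps times the attribution cost).
    """
    if n_steps * step_frac > 1 + 1e-9:
        raise ValueError("n_steps * step_frac must not exceed 1")
    records = list(records)
    labels = np.asarray(labels)
    cfg = config or MethodConfig()
    net = trained_model.net_ if hasattr(trained_model, "net_") else trained_model
    base_scores = np.atleast_1d(net.logits(np.stack(records)))
    base_auroc = auroc(base_scores, labels)

    result = {}
    fractions = [round(step_frac * s, 10) for s in range(n_steps + 1)]
    for m in methods:
        if rankings_override and m in rankings_override:
            rankings = rankings_override[m]
        else:
            rankings = [rank_points_abs(_attr(m, trained_model, x, cfg, baselines))
                        for x in records]
        rng = np.random.default_rng(seed)
        sigs = [x.copy() for x in records]
        masks = [np.zeros(x.shape, bool) for x in records]
        currs = [base_auroc]
        for _ in range(n_steps):
            if recompute_ranking and not (rankings_override and m in rankings_override):
                rankings = [rank_points_abs(_attr(m, trained_model, s, cfg, baselines))
                            for s in sigs]
            for i in range(len(sigs)):
                sigs[i], masks[i] = perturb_step(sigs[i], masks[i], rankings[i],
                                                 step_frac, noise_sd, rng, noise_mode)
            scores = np.atleast_1d(net.logits(np.stack(sigs)))
            currs.append(auroc(scores, labels))
        result[m] = currs
    return PerturbationTrajectory(list(range(n_steps + 1)), fractions, result)


def oracle_ranking(record_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth-first ranking: planted-feature points (shuffled) first."""
    flat = record_mask.ravel()
    inside = np.flatnonzero(flat)
    outside = np.flatnonzero(~flat)
    return np.concatenate([rng.permutation(inside), rng.permutation(outside)])


def random_ranking(shape, rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(int(np.prod(shape)))
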