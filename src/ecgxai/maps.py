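"""Attribution-map post-processing: smoothing, similarity, ranking, aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import rankdata

from .attribution import AttributionMap
from .exceptions import ConfigurationError


def _values(m):
    return m.values if isinstance(m, AttributionMap) else np.asarray(m, float)


def savgol_smooth(map_, window: int = 31, polyorder: int = 3):
    """Savitzky-Golay smoothing applied independently per lead row.

    Defaults are a 31-sample window with a third-order polynomial, which
    suppresses high-frequency gradient noise while reproducing any polynomial
    of degree <= 3 exactly. Edges use polynomial extrapolation of the
    terminal fits (scipy's 'interp' mode).
    """
    v = _values(map_)
    if window % 2 != 1:
        raise ConfigurationError("window must be odd")
    if polyorder >= window:
        raise ConfigurationError("polyorder must be < window")
    if window > v.shape[-1]:
        raise ConfigurationError(f"window {window} exceeds record length {v.shape[-1]}")
    out = savgol_filter(v, window, polyorder, axis=-1, mode="interp")
    if isinstance(map_, AttributionMap):
        return AttributionMap(out, map_.method_id, map_.target, map_.model_tag,
                              map_.config_hash)
    return out


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    kind: str
    n_points: int
    degenerate_flag: bool        # True only when every lead was constant
    n_degenerate_leads: int = 0


def _lead_corr(a: np.ndarray, b: np.ndarray, kind: str):
    """Correlation of two lead rows; None marks a degenerate (constant) row."""
    if kind == "spearman":
        a, b = rankdata(a), rankdata(b)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return None
    # grouping keeps similarity(A, B) == similarity(B, A) bit-exact: elementwise
    # products commute and (sa * sb) is evaluated before scaling by n
    return float(np.sum((a - a.mean()) * (b - b.mean())) / (len(a) * (sa * sb)))


def similarity(mapA, mapB, kind: str = "pearson", pooled: bool = False) -> SimilarityScore:
    """Per-lead correlation of two maps, averaged (unweighted) over the 8 leads.

    The Spearman variant ranks within each lead first. A constant row on
    either side contributes 0 to the mean and is counted as degenerate; the
    score is flagged degenerate only if every lead was constant (then the
    value is exactly 0). ``pooled=True`` switches to the sensitivity-analysis
    variant: one correlation over all leads and samples flattened together.
    """
    if kind not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation kind '{kind}'")
    a, b = _values(mapA), _values(mapB)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if pooled:
        c = _lead_corr(a.ravel(), b.ravel(), kind)
        return SimilarityScore(c if c is not None else 0.0, kind, a.size,
                               c is None, int(c is None))
    per_lead = [_lead_corr(a[i], b[i], kind) for i in range(a.shape[0])]
    n_deg = sum(1 for c in per_lead if c is None)
    vals = [0.0 if c is None else c for c in per_lead]
    value = float(np.mean(vals))
    all_deg = n_deg == a.shape[0]
    return SimilarityScore(0.0 if all_deg else value, kind, a.size, all_deg, n_deg)


def rank_points_abs(map_) -> np.ndarray:
    """Flat indices (lead-major) of all points, descending |value|.

    Ties break by (lead index, time index) ascending, so the order is a
    deterministic total order.
    """
    v = _values(map_)
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite values")
    n_leads, L = v.shape
    lead_idx, time_idx = np.divmod(np.arange(v.size), L)
    order = np.lexsort((time_idx, lead_idx, -np.abs(v).ravel()))
    return order


def aggregate(scores: pd.DataFrame, group_keys, value_col: str = "value",
              ddof: int = 1) -> pd.DataFrame:
    """Mean +/- SD tables over grouped similarity scores.

    ``scores`` is long-format with one row per measured correlation and
    arbitrary key columns (method/pair, class, seed, ...). SD is the sample
    standard deviation (ddof=1) by default — seeds are a sample of possible
    initializations — and 0 for singleton groups. Groups that would be empty
    after dropping NaNs are omitted with a warning rather than reported as 0.
    """
    import warnings

    if scores.empty:
        raise ValueError("no scores to aggregate")
    rows = []
    for key, grp in scores.groupby(list(group_keys), sort=True):
        vals = grp[value_col].dropna().to_numpy(float)
        if len(vals) == 0:
            warnings.warn(f"group {key}: no valid scores, omitted")
            continue
        sd = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
        row = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        row.update({"mean": float(np.mean(vals)), "sd": sd, "n": len(vals)})
        if "degenerate" in grp.columns:
            row["degenerate_count"] = int(grp["degenerate"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
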