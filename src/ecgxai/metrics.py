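"""Binary-classifier evaluation: AUROC, AUPRC, Youden threshold, 2x2 metrics."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve


@dataclass(frozen=True)
class Metrics:
    auroc: float
    auprc: float
    precision: float
    recall: float
    accuracy: float
    f1: float
    specificity: float
    threshold: float

    def as_dict(self) -> dict:
        return asdict(self)


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; AUROC/threshold undefined")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (equals the Mann-Whitney pairwise statistic)."""
    return float(roc_auc_score(_check_two_classes(labels), np.asarray(scores, float)))


def auprc(scores, labels) -> float:
    """Average precision (area under the precision-recall curve)."""
    return float(average_precision_score(_check_two_classes(labels), np.asarray(scores, float)))


def youden_threshold(scores, labels) -> float:
    """Score cut-point maximizing Youden's J = sensitivity + specificity - 1.

    The maximizer is searched over the observed score cut-points (ROC curve
    vertices). Ties are broken toward the lowest threshold achieving the
    maximal J so that recall is not sacrificed.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, float)
    fpr, tpr, thr = roc_curve(labels, scores)
    if len(thr) > 1:  # drop sklearn's predict-nothing sentinel: only observed cuts
        fpr, tpr, thr = fpr[1:], tpr[1:], thr[1:]
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = lowest
    return float(thr[best])


def compute_metrics(scores, labels, threshold: float) -> Metrics:
    """All reported figures at a fixed probability threshold.

    Predictions are positive where score >= threshold. "Micro F1" of a binary
    task reduces to the standard F1 of the positive class, which is what is
    reported here.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / len(labels)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return Metrics(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        specificity=specificity,
        threshold=float(threshold),
    )
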