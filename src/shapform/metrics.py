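"""Performance indices for imbalanced binary classification, from scratch.

AUROC uses the concordance-pair (Mann-Whitney) formulation with half credit
for ties; AUPRC is step-wise average precision (no trapezoidal interpolation,
which inflates the area under class imbalance).  Also hosts Cronbach's alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np


class SingleClassMetricError(ValueError):
    """Rank metrics are undefined when only one class is present."""


@dataclass
class MetricsReport:
    accuracy: float
    auroc: float
    precision: float
    recall: float
    balanced_accuracy: float
    auprc: float
    threshold: float = 0.5

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    sorted_x = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), via the rank-sum identity."""
    y = np.asarray(y).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise SingleClassMetricError("auroc needs both classes")
    ranks = _midranks(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def average_precision(y: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise AP: sum over the sorted sweep of (R_n - R_{n-1}) * P_n.

    Ties in scores are broken by original position (stable descending sort)
    so the result is deterministic.
    """
    y = np.asarray(y).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise SingleClassMetricError("average precision needs both classes")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    precision = tp / np.arange(1, y.size + 1)
    return float(precision[y_sorted == 1].sum() / n_pos)


def thresholded_metrics(y, scores, threshold: float = 0.5) -> dict:
    """Confusion-matrix indices at ``threshold``; defined for any label mix."""
    y = np.asarray(y).ravel().astype(int)
    scores = np.asarray(scores, dtype=float).ravel()
    if y.size != scores.size:
        raise ValueError("y and scores are not aligned")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    accuracy = (tp + tn) / y.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    balanced = (recall + specificity) / 2.0
    return {
        "accuracy": float(accuracy),
        "precision": float(precision),
        "recall": float(recall),
        "balanced_accuracy": float(balanced),
        "threshold": float(threshold),
    }


def compute_metrics(y, scores, threshold: float = 0.5) -> MetricsReport:
    """All six indices: thresholded ones plus the two rank metrics.

    ``scores`` are probabilities (or any monotone score; the threshold is
    applied as given).  Single-class ``y`` raises
    :class:`SingleClassMetricError` for the rank metrics; use
    :func:`thresholded_metrics` when only the confusion-matrix indices are
    needed in that regime.
    """
    t = thresholded_metrics(y, scores, threshold)
    y = np.asarray(y).ravel().astype(int)
    scores = np.asarray(scores, dtype=float).ravel()
    return MetricsReport(
        accuracy=t["accuracy"],
        auroc=auroc(y, scores),
        precision=t["precision"],
        recall=t["recall"],
        balanced_accuracy=t["balanced_accuracy"],
        auprc=average_precision(y, scores),
        threshold=float(threshold),
    )


def cronbach_alpha(responses) -> float:
    """alpha = p/(p-1) * (1 - sum item variances / total-score variance)."""
    values = getattr(responses, "values", responses)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need an n x p matrix with p >= 2")
    p = values.shape[1]
    item_var = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero")
    return float(p / (p - 1) * (1.0 - item_var.sum() / total_var))
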