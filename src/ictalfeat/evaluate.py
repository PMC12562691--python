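"""From-scratch classification metrics: confusion accounting, weighted
precision/recall/F1, and weighted one-vs-rest multiclass AUC.

Conventions (fixed and tested):

* class order is alphabetical over the six seizure-type codes;
* multiclass accuracy is trace(counts)/total (micro-averaged binary
  accuracy);
* per-class precision with no predicted positives is 0 before weighting;
* AUC per class is the Mann-Whitney rank statistic with midranks for
  ties (equivalent to trapezoidal ROC integration); classes absent from
  the truth are excluded and the support weights renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .recording import CLASS_ORDER


@dataclass
class ConfusionMatrix:
    """Integer confusion counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over class_order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percent(self) -> np.ndarray:
        """Row percentages; rows with zero support are left as 0 (omitted)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, self.counts / np.maximum(sums, 1) * 100.0, 0.0)
        return pct


def confusion(true_labels, pred_labels,
              class_order: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    """Exact confusion counts for pooled predictions."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label arrays differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def weighted_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Support-weighted one-vs-rest (precision, recall, F1)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    support = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    w = support / support.sum()
    return float(w @ precision), float(w @ recall), float(w @ f1)


def _binary_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("binary AUC needs both classes present")
    ranks = rankdata(scores)
    rank_sum = ranks[truth.astype(bool)].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def multiclass_auc(true_labels, prob_matrix,
                   class_order: tuple[str, ...] = CLASS_ORDER) -> float:
    """Support-weighted one-vs-rest AUC from class-probability columns."""
    true_labels = np.asarray(true_labels)
    prob = np.asarray(prob_matrix, dtype=float)
    if prob.shape != (true_labels.size, len(class_order)):
        raise ValueError("probability matrix shape mismatch")
    row_sums = prob.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    aucs, weights = [], []
    for j, cls in enumerate(class_order):
        pos = (true_labels == cls).astype(float)
        n_pos = int(pos.sum())
        if n_pos == 0:
            continue  # class absent from the truth: excluded, weights renormalize
        if n_pos == true_labels.size:
            continue
        aucs.append(_binary_auc(pos, prob[:, j]))
        weights.append(n_pos)
    if not aucs:
        raise ValueError("no class has both positives and negatives")
    weights = np.asarray(weights, dtype=float)
    return float(np.average(aucs, weights=weights))


def metrics_from_predictions(true_labels, pred_labels, prob_matrix,
                             class_order: tuple[str, ...] = CLASS_ORDER,
                             ) -> dict[str, float]:
    """All five headline metrics for one set of pooled/fold predictions."""
    cm = confusion(true_labels, pred_labels, class_order)
    precision, recall, f1 = weighted_metrics(cm)
    return {
        "accuracy": accuracy(cm),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": multiclass_auc(true_labels, prob_matrix, class_order),
    }
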