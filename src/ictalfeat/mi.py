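"""Mutual information between continuous features and the discrete class label.

The estimator is the nearest-neighbour method for a continuous variable
against a discrete one: for each sample, the distance to its k-th nearest
neighbour *within the same class* defines a radius, and the number of
samples of any class inside that radius enters a digamma identity,

    I(X;Y) = psi(N) + psi(k) - <psi(N_y)> - <psi(m_i)>,

clipped at zero.  A tiny seeded jitter (SD = 1e-10 * max(1, mean|x|))
breaks ties deterministically; the per-column jitter seed is derived from
the column's content, so duplicated columns always receive identical
scores.  Scores are reported in nats.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma


@dataclass
class MIScores:
    """Per-feature MI estimates (nats, >= 0) plus estimator metadata."""

    scores: dict[str, float]
    k_neighbors: int = 3
    seed: int = 0

    def __getitem__(self, name: str) -> float:
        return self.scores[name]

    def __len__(self) -> int:
        return len(self.scores)

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.scores[n] for n in names])


@dataclass
class SelectionResult:
    """Top-k features by MI, in descending-score order."""

    selected_names: list[str]
    k: int
    scores: MIScores


def mi_continuous_discrete(x: np.ndarray, y: np.ndarray, k_neighbors: int = 3,
                           seed: int = 0) -> float:
    """MI (nats) between a continuous feature ``x`` and discrete labels ``y``."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to estimate MI")
    if np.ptp(x) == 0:
        return 0.0

    rng = np.random.default_rng(seed)
    x = x + rng.normal(0.0, 1e-10 * max(1.0, float(np.mean(np.abs(x)))), x.size)

    n = x.size
    radius = np.zeros(n)
    label_count = np.zeros(n, dtype=int)
    k_used = np.zeros(n, dtype=int)
    for cls, cnt in zip(classes, counts):
        mask = y == cls
        label_count[mask] = cnt
        if cnt <= 1:
            continue
        k = min(k_neighbors, cnt - 1)
        k_used[mask] = k
        pts = x[mask, None]
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=k + 1)
        radius[mask] = dist[:, -1]

    keep = label_count > 1
    if not np.any(keep):
        raise ValueError("every class is a singleton; MI undefined")
    n_eff = int(keep.sum())
    tree_all = cKDTree(x[keep, None])
    # shrink the radius one ulp so the count is strictly-within-kth-distance
    r = np.nextafter(radius[keep], 0)
    m_i = tree_all.query_ball_point(x[keep, None], r, return_length=True)
    m_i = np.maximum(m_i, 1)
    mi = (digamma(n_eff) + np.mean(digamma(k_used[keep]))
          - np.mean(digamma(label_count[keep])) - np.mean(digamma(m_i)))
    return float(max(0.0, mi))


def _column_seed(col: np.ndarray, seed: int) -> int:
    """Deterministic per-column jitter seed derived from the column content."""
    return (zlib.crc32(np.ascontiguousarray(col).tobytes()) ^ (seed & 0xFFFFFFFF)) & 0x7FFFFFFF


def score_all(fm, k_neighbors: int = 3, seed: int = 0) -> MIScores:
    """MI score for every feature column against the segment labels."""
    labels = np.asarray(fm.labels)
    if np.unique(labels).size < 2:
        raise ValueError("feature matrix labels contain fewer than 2 classes")
    scores = {}
    for j, name in enumerate(fm.names):
        col = fm.values[:, j]
        scores[name] = mi_continuous_discrete(
            col, labels, k_neighbors=k_neighbors, seed=_column_seed(col, seed))
    return MIScores(scores=scores, k_neighbors=k_neighbors, seed=seed)


def select_top_k(scores: MIScores, k: int = 30) -> SelectionResult:
    """Keep the ``min(k, n)`` highest-MI features; ties break by name."""
    if k < 1:
        raise ValueError("k must be at least 1")
    ordered = sorted(scores.scores.items(), key=lambda item: (-item[1], item[0]))
    selected = [name for name, _ in ordered[:min(k, len(ordered))]]
    return SelectionResult(selected_names=selected, k=k, scores=scores)
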