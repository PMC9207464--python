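"""Evaluation metrics: clustering agreement and marker-selection quality."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, confusion_matrix

__all__ = [
    "adjusted_rand_index",
    "SelectionMetrics",
    "selection_metrics",
    "match_clusters",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (permutation-model ARI)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least two items")
    return float(adjusted_rand_score(labels_a, labels_b))


@dataclass
class SelectionMetrics:
    """Pooled marker-selection quality over a set of replicates.

    Sensitivity is the fraction of (active marker, replicate) pairs where the
    marker was selected; specificity the fraction of (inactive marker,
    replicate) pairs where it was not.  A marker counts as selected in a
    replicate when any non-reference class carries a nonzero coefficient
    for it.
    """

    sensitivity: float
    specificity: float
    selection_counts: dict[int, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")


def selection_metrics(
    true_support, selected_per_replicate, L: int
) -> SelectionMetrics:
    """Pool selection sensitivity/specificity over replicates.

    ``true_support`` is the set of truly active marker indices;
    ``selected_per_replicate`` a list of per-replicate selected marker sets
    (marker indices, or (class, marker) pairs — reduced to markers).
    """
    true_support = {int(m) for m in true_support}
    if not all(0 <= m < L for m in true_support):
        raise ValueError("true_support must be a subset of {0..L-1}")
    reps = list(selected_per_replicate)
    if not reps:
        raise ValueError("need at least one replicate")

    def markers_of(sel) -> set[int]:
        out = set()
        for s in sel:
            if isinstance(s, (tuple, list, np.ndarray)):
                out.add(int(s[1]))
            else:
                out.add(int(s))
        return out

    counts: dict[int, int] = {}
    tp = fp = 0
    for sel in reps:
        ms = markers_of(sel)
        for m in ms:
            counts[m] = counts.get(m, 0) + 1
        tp += len(ms & true_support)
        fp += len(ms - true_support)
    R = len(reps)
    n_active = len(true_support)
    n_inactive = L - n_active
    sens = tp / (n_active * R) if n_active else float("nan")
    spec = (n_inactive * R - fp) / (n_inactive * R) if n_inactive else float("nan")
    return SelectionMetrics(sens, spec, counts)


def match_clusters(true_labels, est_labels, K: int) -> np.ndarray:
    """Permutation ``perm`` maximizing agreement: est class j plays true class perm[j].

    Solved as an optimal assignment on the confusion matrix, so comparing
    label-switched fits against the truth is well defined.
    """
    true_labels = np.asarray(true_labels, dtype=int)
    est_labels = np.asarray(est_labels, dtype=int)
    cm = confusion_matrix(true_labels, est_labels, labels=np.arange(K))
    rows, cols = linear_sum_assignment(-cm)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return perm
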