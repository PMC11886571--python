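"""Partition-agreement metrics: ARI, NMI, and Hungarian-matched accuracy.

All three are invariant to relabeling of either partition.  ACC resolves the
arbitrary cluster numbering by an optimal one-to-one assignment between
predicted and true cluster ids (Hungarian algorithm) before counting the
fraction of agreeing spots.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix


def _check_lengths(labels_true, labels_pred):
    labels_true = np.asarray(labels_true).ravel()
    labels_pred = np.asarray(labels_pred).ravel()
    if labels_true.shape != labels_pred.shape:
        raise ValueError(
            f"label vectors differ in length: {labels_true.size} vs {labels_pred.size}"
        )
    if labels_true.size == 0:
        raise ValueError("empty label vectors")
    return labels_true, labels_pred


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 at chance."""
    labels_true, labels_pred = _check_lengths(labels_true, labels_pred)
    return float(adjusted_rand_score(labels_true, labels_pred))


def nmi(labels_true, labels_pred) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    labels_true, labels_pred = _check_lengths(labels_true, labels_pred)
    return float(
        normalized_mutual_info_score(
            labels_true, labels_pred, average_method="arithmetic"
        )
    )


def acc(labels_true, labels_pred) -> float:
    """Clustering accuracy after optimal one-to-one cluster matching.

    Builds the contingency table, solves the maximum-agreement assignment
    between predicted and true cluster ids, and returns the matched
    fraction.  With more predicted clusters than true ones (or vice versa),
    unmatched clusters simply contribute no agreement.
    """
    labels_true, labels_pred = _check_lengths(labels_true, labels_pred)
    table = contingency_matrix(labels_true, labels_pred)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / labels_true.size)


def evaluate(labels_true, labels_pred) -> dict:
    """All three metrics in one dict."""
    return {
        "acc": acc(labels_true, labels_pred),
        "ari": ari(labels_true, labels_pred),
        "nmi": nmi(labels_true, labels_pred),
    }
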