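"""Clustering evaluation: adjusted Rand index, normalized mutual
information, and silhouette.

ARI and NMI are computed from the contingency table of the two partitions;
both are invariant to relabeling. NMI uses the 2·MI/(H(U)+H(V))
normalization with natural logarithms (the base cancels).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import silhouette_score as _sk_silhouette


def _check_pair(U, V) -> tuple[np.ndarray, np.ndarray]:
    U = np.asarray(U).ravel()
    V = np.asarray(V).ravel()
    if U.shape != V.shape:
        raise ValueError("label vectors must have equal length")
    if U.size == 0:
        raise ValueError("label vectors are empty")
    return U, V


def _contingency(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    _, ui = np.unique(U, return_inverse=True)
    _, vi = np.unique(V, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def adjusted_rand_index(U, V) -> float:
    """Pair-counting Rand index adjusted for chance via its permutation-model
    expectation: (RI − E[RI]) / (max RI − E[RI])."""
    U, V = _check_pair(U, V)
    nij = _contingency(U, V)
    a = nij.sum(axis=1)
    b = nij.sum(axis=0)
    n = nij.sum()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(nij).sum()
    sum_a = comb2(a).sum()
    sum_b = comb2(b).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-singletons/all-one)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def normalized_mutual_information(U, V) -> float:
    """2·MI(U,V)/(H(U)+H(V)) from the empirical joint distribution.

    Two constant labelings are identical partitions and score 1.
    """
    U, V = _check_pair(U, V)
    nij = _contingency(U, V).astype(float)
    n = nij.sum()
    pij = nij / n
    pu = pij.sum(axis=1)
    pv = pij.sum(axis=0)
    hu = float(-(pu[pu > 0] * np.log(pu[pu > 0])).sum())
    hv = float(-(pv[pv > 0] * np.log(pv[pv > 0])).sum())
    if hu == 0.0 and hv == 0.0:
        return 1.0
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pu, pv)[nz])).sum())
    return 2.0 * mi / (hu + hv)


def silhouette(Z: np.ndarray, labels, metric: str = "euclidean") -> float:
    """Mean silhouette coefficient of `labels` on embedding `Z`."""
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(_sk_silhouette(np.asarray(Z), labels, metric=metric))
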