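"""Hierarchical clustering of the LCS distance matrix with silhouette-based
selection of the number of clusters.

Average linkage is the default: LCS distances are arbitrary dissimilarities
without a Euclidean embedding, which rules out Ward on first principles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

__all__ = ["ClusteringResult", "agglomerative_cluster", "silhouette_and_select_k", "cluster_sequences"]


@dataclass
class ClusteringResult:
    ids: list
    labels: np.ndarray  # cluster labels in 1..k, aligned with ids
    k: int
    silhouette_by_k: dict[int, float]
    linkage: str


def _check_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    return D


def agglomerative_cluster(D: np.ndarray, k: int, method: str = "average") -> np.ndarray:
    """Cut an agglomerative dendrogram of the precomputed distances at k
    clusters.  Labels are renumbered 1..k by order of first appearance so
    the output is deterministic for a given matrix."""
    D = _check_matrix(D)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for n={n}")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(squareform(D, checks=False), method=method)
    # cut by merge count (first n-k merges) rather than by height: with tied
    # merge heights a height threshold cannot always realize exactly k groups
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    raw = np.array([find(i) for i in range(n)])
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[i] = relabel[lab]
    return out


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b) from a precomputed
    distance matrix; singleton clusters contribute s(i) = 0."""
    return float(np.mean(silhouette_samples(D, labels, metric="precomputed")))


def silhouette_and_select_k(
    D: np.ndarray,
    k_range=range(2, 9),
    method: str = "average",
    ids=None,
) -> ClusteringResult:
    """Cluster at each k in ``k_range`` and keep the k with the largest mean
    silhouette width (smallest k wins ties)."""
    D = _check_matrix(D)
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("k_range must be non-empty")
    n = D.shape[0]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError("every k must satisfy 2 <= k <= n-1")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        lab = agglomerative_cluster(D, k, method=method)
        labels_by_k[k] = lab
        sil[k] = mean_silhouette(D, lab)
    best = max(sorted(sil), key=lambda k: sil[k])
    return ClusteringResult(
        ids=list(ids) if ids is not None else list(range(n)),
        labels=labels_by_k[best],
        k=best,
        silhouette_by_k=sil,
        linkage=method,
    )


def cluster_sequences(sequences, k_range=range(2, 9), method: str = "average", norm: str = "max") -> ClusteringResult:
    """Convenience wrapper: LCS distances -> dendrogram -> silhouette model
    selection, straight from a dict of patient sequences."""
    from .lcs import pairwise_distance_matrix

    ids, D = pairwise_distance_matrix(sequences, norm=norm)
    return silhouette_and_select_k(D, k_range=k_range, method=method, ids=ids)
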