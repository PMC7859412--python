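"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (double loops, exhaustive search) and
shares no code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_euclidean_matrix(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    return D


def naive_average_linkage_cophenetic(D: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix of the average-linkage (UPGMA) merge tree.

    Clusters are merged greedily by the smallest average of *original*
    pairwise distances between their members; the cophenetic distance of two
    leaves is the merge height at which they first share a cluster.
    """
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
    return coph


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))


def naive_dunn(D: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    diam = 0.0
    for u in uniq:
        idx = np.flatnonzero(labels == u)
        for i in idx:
            for j in idx:
                diam = max(diam, D[i, j])
    between = np.inf
    for a, b in itertools.combinations(uniq, 2):
        for i in np.flatnonzero(labels == a):
            for j in np.flatnonzero(labels == b):
                between = min(between, D[i, j])
    if diam == 0:
        return np.inf if between > 0 else 0.0
    return between / diam


def pam_cost(D: np.ndarray, medoids) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def exhaustive_pam(D: np.ndarray, k: int) -> float:
    """Cost of the globally optimal medoid set (exhaustive search)."""
    n = D.shape[0]
    return min(pam_cost(D, m) for m in itertools.combinations(range(n), k))


def naive_wk(X: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of (pairwise squared distances) / (2 * cluster size)."""
    total = 0.0
    for u in np.unique(labels):
        idx = np.flatnonzero(labels == u)
        dr = 0.0
        for i in idx:
            for j in idx:
                dr += ((X[i] - X[j]) ** 2).sum()
        total += dr / (2.0 * len(idx))
    return total


def ols_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal-equations simple OLS (slope, intercept)."""
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return slope, ym - slope * xm
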