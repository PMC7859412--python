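"""Clustering of standardised onset curves with full model selection.

The procedure mirrors how the disease-onset clusters are chosen end to end:

1. Pairwise Euclidean distances between standardised 64-point curves.
2. Linkage selection for hierarchical agglomerative clustering by the
   cophenetic correlation coefficient (how faithfully the dendrogram's merge
   heights reproduce the original distances).
3. The number of clusters k, per algorithm, by the Tibshirani gap statistic
   against a uniform reference distribution.
4. Algorithm selection (hierarchical vs k-means vs PAM vs spectral), each at
   its own gap-chosen k, by the Dunn validation index.
5. Main/outlier split: clusters with >= 3 diseases are "main" clusters,
   relabelled 1..M in descending order of their members' median onset ages
   (cluster 1 = oldest-onset); clusters with <= 2 diseases are outliers.

The heavy lifting for the standard algorithms is delegated: hierarchical
trees, cuts and cophenetic distances to scipy.cluster.hierarchy, k-means and
spectral embedding to scikit-learn. PAM (classic BUILD + steepest-descent
SWAP), the gap statistic and the Dunn index are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.utils.validation import check_array

from .exceptions import ArdkitError

__all__ = [
    "ALGORITHMS",
    "LINKAGES",
    "distance_matrix",
    "hierarchical_cluster",
    "cophenetic_correlation",
    "select_linkage",
    "kmeans_cluster",
    "pam_cluster",
    "pam_medoids",
    "spectral_cluster",
    "within_cluster_dispersion",
    "gap_statistic",
    "GapResult",
    "dunn_index",
    "OnsetCurveClusterer",
    "split_main_outlier",
]

ALGORITHMS = ("hierarchical", "kmeans", "pam", "spectral")
LINKAGES = ("single", "complete", "average", "weighted")

MAIN_CLUSTER_MIN_SIZE = 3


# ---------------------------------------------------------------------------
# distances and hierarchical clustering


def distance_matrix(X) -> np.ndarray:
    """Square matrix of Euclidean distances between curve rows."""
    X = check_array(X)
    return squareform(pdist(X))


def _condensed(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, float)
    if dm.ndim == 1:
        return dm
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T) or np.any(np.diag(dm) != 0):
        raise ValueError("distance matrix must be square symmetric with zero diagonal")
    return squareform(dm, checks=False)


def linkage_tree(dm, method: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) from a distance matrix.

    Deterministic for a fixed input; merge ties are resolved by scipy's
    nearest-neighbour-chain order.
    """
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    return hierarchy.linkage(_condensed(dm), method=method)


def cut_tree_k(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut a merge tree into exactly k clusters (labels 0..k-1)."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}")
    return hierarchy.cut_tree(Z, n_clusters=k).ravel()


def hierarchical_cluster(dm, linkage: str = "average", k: int = 2) -> np.ndarray:
    """Average-linkage (or other) agglomerative clustering cut at k clusters."""
    return cut_tree_k(linkage_tree(dm, linkage), k)


def cophenetic_correlation(dm, Z: np.ndarray) -> float:
    """Pearson correlation between original and cophenetic (merge-height) distances."""
    cond = _condensed(dm)
    n = Z.shape[0] + 1
    if n < 3:
        raise ArdkitError("cophenetic correlation undefined for fewer than 3 leaves")
    r, _ = hierarchy.cophenet(Z, cond)
    return float(r)


def select_linkage(dm, candidates=LINKAGES) -> tuple[str, dict[str, float]]:
    """Pick the linkage whose dendrogram best preserves the distances.

    Returns (best_linkage, {linkage: cophenetic r}); ties go to the earlier
    candidate in the given order.
    """
    candidates = tuple(candidates)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate linkage")
    scores = {m: cophenetic_correlation(dm, linkage_tree(dm, m)) for m in candidates}
    best = max(candidates, key=lambda m: scores[m])
    return best, scores


# ---------------------------------------------------------------------------
# flat clustering algorithms


def kmeans_cluster(X, k: int, seed: int | None = None, n_init: int = 10) -> np.ndarray:
    """k-means on the curves themselves (k-means++ init, best of n_init runs)."""
    X = np.asarray(X, float)
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    for attempt in range(3):
        km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                    random_state=None if seed is None else seed + attempt)
        labels = km.fit_predict(X)
        if np.unique(labels).size == k:
            return labels
    raise ArdkitError(f"k-means produced an empty cluster at k={k} after retries")


def pam_medoids(dm, k: int) -> np.ndarray:
    """Medoid indices from classic PAM: BUILD then steepest-descent SWAP.

    Operates purely on the distance matrix and is deterministic; ties are
    broken by lowest index. The result is swap-optimal (no single
    medoid/non-medoid exchange lowers the total cost), the defining
    stopping condition of PAM — not necessarily the global optimum.
    """
    D = np.asarray(dm, float)
    if D.ndim == 1:
        D = squareform(D)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}")

    # BUILD: greedily add the medoid giving the largest cost reduction
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        reduction = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        reduction[medoids] = -np.inf
        medoids.append(int(np.argmax(reduction)))

    # SWAP: repeatedly apply the single best improving (medoid, candidate) swap
    medoids = np.asarray(medoids)
    while True:
        dist_to_med = D[:, medoids]
        order = np.argsort(dist_to_med, axis=1)
        nearest_i = order[:, 0]
        dn = dist_to_med[np.arange(n), nearest_i]
        ds = dist_to_med[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        cost = dn.sum()

        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            # distance to the nearest medoid once medoids[mi] is removed
            base = np.where(nearest_i == mi, ds, dn)
            trial_cost = np.minimum(base[:, None], D).sum(axis=0)  # per candidate h
            trial_cost[medoids] = np.inf
            h = int(np.argmin(trial_cost))
            delta = trial_cost[h] - cost
            if delta < best_delta:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    return medoids


def pam_cluster(dm, k: int, seed: int | None = None) -> np.ndarray:
    """PAM cluster labels (see :func:`pam_medoids`; the seed is accepted for
    interface symmetry with the stochastic algorithms only)."""
    D = np.asarray(dm, float)
    if D.ndim == 1:
        D = squareform(D)
    return np.argmin(D[:, pam_medoids(D, k)], axis=1)


def spectral_cluster(X, k: int, seed: int | None = None) -> np.ndarray:
    """Spectral clustering: Gaussian affinity on Euclidean distances, with
    bandwidth = median pairwise distance, normalised Laplacian embedding,
    then k-means on the embedding."""
    X = np.asarray(X, float)
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    D = squareform(pdist(X))
    sigma = np.median(D[np.triu_indices_from(D, k=1)])
    if sigma <= 0:
        sigma = 1.0
    A = np.exp(-(D**2) / (2.0 * sigma**2))
    for attempt in range(3):
        sc = SpectralClustering(
            n_clusters=k, affinity="precomputed",
            random_state=None if seed is None else seed + attempt,
            assign_labels="kmeans",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # graph-connectivity chatter
            labels = sc.fit_predict(A)
        if np.unique(labels).size == k:
            return labels
    raise ArdkitError(f"spectral clustering produced an empty cluster at k={k}")


# ---------------------------------------------------------------------------
# gap statistic


def within_cluster_dispersion(X, labels) -> float:
    """W_k = sum over clusters r of D_r / (2 n_r), with D_r the sum of all
    pairwise squared Euclidean distances inside cluster r (equivalently the
    within-cluster sum of squared deviations from the centroid)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        mu = pts.mean(axis=0)
        total += float(((pts - mu) ** 2).sum())
    return total


@dataclass
class GapResult:
    ks: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    log_w: np.ndarray
    log_w_ref: np.ndarray  # mean over reference draws
    chosen_k: int
    algorithm: str = ""


def _labeller(algorithm: str, X: np.ndarray, seed: int | None, linkage: str):
    """Per-dataset k -> labels closure (expensive shared work done once)."""
    if algorithm == "hierarchical":
        Z = linkage_tree(distance_matrix(X), linkage)
        return lambda k: cut_tree_k(Z, k)
    if algorithm == "kmeans":
        return lambda k: kmeans_cluster(X, k, seed=seed)
    if algorithm == "pam":
        D = distance_matrix(X)
        return lambda k: pam_cluster(D, k)
    if algorithm == "spectral":
        return lambda k: spectral_cluster(X, k, seed=seed)
    raise ValueError(f"algorithm must be one of {ALGORITHMS}")


def _log_w(X, labeller, ks) -> np.ndarray:
    out = np.empty(len(ks))
    tiny = np.finfo(float).tiny
    for i, k in enumerate(ks):
        w = within_cluster_dispersion(X, labeller(int(k)))
        if w <= 0:
            warnings.warn(f"W_k collapsed to zero at k={k}; flooring", RuntimeWarning)
            w = tiny
        out[i] = np.log(w)
    return out


def _reference_sampler(X: np.ndarray, reference: str):
    """Uniform reference distribution for the gap statistic.

    ``"pca"`` samples uniformly in the box aligned with the data's principal
    axes (Tibshirani's method (b), appropriate when the data are elongated
    along a low-dimensional manifold, as standardised onset curves are);
    ``"box"`` uses the plain per-feature range (method (a)).
    """
    if reference == "box":
        lo, hi = X.min(axis=0), X.max(axis=0)
        return lambda rng: rng.uniform(lo, hi, size=X.shape)
    if reference == "pca":
        mu = X.mean(axis=0)
        Xc = X - mu
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        Xp = Xc @ vt.T
        lo, hi = Xp.min(axis=0), Xp.max(axis=0)
        return lambda rng: rng.uniform(lo, hi, size=Xp.shape) @ vt + mu
    raise ValueError("reference must be 'pca' or 'box'")


def gap_statistic(
    X,
    algorithm: str = "hierarchical",
    k_max: int = 30,
    n_refs: int = 50,
    seed: int | None = None,
    linkage: str = "average",
    reference: str = "pca",
) -> GapResult:
    """Tibshirani gap statistic for choosing the number of clusters.

    Gap(k) = mean_b log W*_kb - log W_k over ``n_refs`` reference datasets
    drawn uniformly over the data's range (in the principal-axes frame by
    default, see :func:`_reference_sampler`); s_k is the reference standard
    deviation inflated by sqrt(1 + 1/B). The chosen k is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}.
    """
    X = check_array(X)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    n = X.shape[0]
    ks = np.arange(1, min(k_max, n - 1) + 1)
    ss = np.random.SeedSequence(0 if seed is None else seed)
    data_seed, ref_entropy = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))

    log_w = _log_w(X, _labeller(algorithm, X, data_seed, linkage), ks)

    sample_ref = _reference_sampler(X, reference)
    rng = np.random.default_rng(ref_entropy)
    ref_log_w = np.empty((n_refs, len(ks)))
    for b in range(n_refs):
        ref = sample_ref(rng)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        ref_log_w[b] = _log_w(ref, _labeller(algorithm, ref, ref_seed, linkage), ks)

    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)

    chosen = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen = int(ks[i])
            break
    return GapResult(ks=ks, gap=gap, s=s, log_w=log_w,
                     log_w_ref=ref_log_w.mean(axis=0), chosen_k=chosen,
                     algorithm=algorithm)


# ---------------------------------------------------------------------------
# Dunn index and algorithm selection


def dunn_index(dm, labels) -> float:
    """Minimum between-cluster distance / maximum within-cluster diameter.

    If every cluster has zero diameter (all member points coincide) while
    clusters are distinct, returns +inf as a sentinel for perfect
    separation.
    """
    D = np.asarray(dm, float)
    if D.ndim == 1:
        D = squareform(D)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ArdkitError("Dunn index requires at least 2 clusters")
    masks = [labels == u for u in uniq]
    diameters = [D[np.ix_(m, m)].max() for m in masks]
    max_diam = max(diameters)
    min_between = min(
        D[np.ix_(masks[i], masks[j])].min()
        for i in range(len(uniq)) for j in range(i + 1, len(uniq))
    )
    if max_diam == 0.0:
        return np.inf if min_between > 0 else 0.0
    return float(min_between / max_diam)


# ---------------------------------------------------------------------------
# estimator running the whole selection procedure


class OnsetCurveClusterer(ClusterMixin, BaseEstimator):
    """Cluster standardised onset curves with full model selection.

    fit(X) with X the (n_diseases, 64) matrix of standardised curves:

    1. chooses the hierarchical linkage by cophenetic correlation,
    2. chooses k for every candidate algorithm by the gap statistic,
    3. chooses the algorithm by the Dunn index at its gap-chosen k
       (ties prefer hierarchical, the reference method).

    Fitted attributes: ``labels_``, ``algorithm_``, ``n_clusters_``,
    ``linkage_``, ``cophenetic_scores_``, ``gap_results_`` (per algorithm),
    ``dunn_scores_``, ``labels_by_algorithm_``, ``linkage_matrix_``.
    """

    def __init__(
        self,
        algorithms: tuple = ALGORITHMS,
        linkages: tuple = LINKAGES,
        k_max: int = 30,
        n_refs: int = 50,
        gap_reference: str = "pca",
        random_state: int | None = None,
    ):
        self.algorithms = algorithms
        self.linkages = linkages
        self.k_max = k_max
        self.n_refs = n_refs
        self.gap_reference = gap_reference
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        algorithms = tuple(self.algorithms)
        unknown = set(algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        dm = distance_matrix(X)

        self.linkage_, self.cophenetic_scores_ = select_linkage(dm, tuple(self.linkages))
        self.linkage_matrix_ = linkage_tree(dm, self.linkage_)

        # fixed per-algorithm seeds derived from random_state, independent of
        # which subset of algorithms is requested
        ss = np.random.SeedSequence(0 if self.random_state is None else self.random_state)
        state = ss.generate_state(len(ALGORITHMS))
        algo_seed = {a: int(s) & 0x7FFFFFFF for a, s in zip(ALGORITHMS, state)}

        self.gap_results_: dict[str, GapResult] = {}
        self.labels_by_algorithm_: dict[str, np.ndarray] = {}
        self.dunn_scores_: dict[str, float] = {}
        for algo in algorithms:
            res = gap_statistic(
                X, algorithm=algo, k_max=self.k_max, n_refs=self.n_refs,
                seed=algo_seed[algo], linkage=self.linkage_,
                reference=self.gap_reference,
            )
            self.gap_results_[algo] = res
            labels = _labeller(algo, X, algo_seed[algo], self.linkage_)(res.chosen_k)
            self.labels_by_algorithm_[algo] = labels
            self.dunn_scores_[algo] = (
                dunn_index(dm, labels) if res.chosen_k >= 2 else -np.inf
            )

        # argmax Dunn; on ties prefer hierarchical, then the listed order
        pref = {a: i for i, a in enumerate(algorithms)}
        self.algorithm_ = max(
            algorithms,
            key=lambda a: (self.dunn_scores_[a], a == "hierarchical", -pref[a]),
        )
        self.labels_ = self.labels_by_algorithm_[self.algorithm_]
        self.n_clusters_ = int(self.gap_results_[self.algorithm_].chosen_k)
        self.n_features_in_ = X.shape[1]
        return self


# ---------------------------------------------------------------------------
# main / outlier partition


def split_main_outlier(labels, disease_ids, median_onsets) -> pd.DataFrame:
    """Split clusters into main (>= 3 diseases) and outlier (<= 2) clusters.

    Main clusters are relabelled 1..M in *descending* order of the
    within-cluster median of their members' median onset ages, so main
    cluster 1 always contains the oldest-onset diseases. Outlier clusters
    are numbered 1..m by the same criterion.

    Parameters
    ----------
    labels : array of raw cluster ids, one per disease
    disease_ids : sequence of labels aligned with ``labels``
    median_onsets : mapping / Series disease_id -> median onset age

    Returns a DataFrame indexed by disease_id with columns ``cluster_raw``,
    ``is_main``, ``main_label`` (1..M or <NA>), ``outlier_label``.
    """
    labels = np.asarray(labels)
    disease_ids = list(disease_ids)
    if len(disease_ids) != labels.size:
        raise ValueError("labels and disease_ids must align")
    med = pd.Series(median_onsets)

    df = pd.DataFrame({"disease_id": disease_ids, "cluster_raw": labels})
    df["median_onset"] = df["disease_id"].map(med)
    if df["median_onset"].isna().any():
        missing = df.loc[df["median_onset"].isna(), "disease_id"].tolist()
        raise ValueError(f"missing median onset age for diseases: {missing}")

    sizes = df.groupby("cluster_raw")["disease_id"].size()
    cluster_med = df.groupby("cluster_raw")["median_onset"].median()
    order = cluster_med.sort_values(ascending=False, kind="mergesort").index

    main_label, outlier_label = {}, {}
    m = o = 0
    for c in order:
        if sizes[c] >= MAIN_CLUSTER_MIN_SIZE:
            m += 1
            main_label[c] = m
        else:
            o += 1
            outlier_label[c] = o
    df["is_main"] = df["cluster_raw"].map(lambda c: c in main_label)
    df["main_label"] = df["cluster_raw"].map(main_label).astype("Int64")
    df["outlier_label"] = df["cluster_raw"].map(outlier_label).astype("Int64")
    return df.drop(columns="median_onset").set_index("disease_id")
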