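import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from ardkit.clustering import (
    LINKAGES,
    OnsetCurveClusterer,
    cophenetic_correlation,
    cut_tree_k,
    distance_matrix,
    dunn_index,
    gap_statistic,
    hierarchical_cluster,
    kmeans_cluster,
    linkage_tree,
    pam_cluster,
    select_linkage,
    spectral_cluster,
    split_main_outlier,
    within_cluster_dispersion,
)
from ardkit.exceptions import ArdkitError

from ._oracles import (
    exhaustive_pam,
    naive_average_linkage_cophenetic,
    naive_dunn,
    naive_euclidean_matrix,
    naive_pearson,
    naive_wk,
    pam_cost,
)

LINE3 = np.array([[0.0], [1.0], [10.0]])  # hand-checkable 1-D instance


class TestDistanceMatrix:
    def test_identical_curves_distance_zero(self):
        X = np.tile([0.2, 0.8], (3, 1))
        assert (distance_matrix(X) == 0).all()

    def test_orthogonal_unit_curves(self):
        D = distance_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(8, 64))
        assert np.allclose(distance_matrix(X), naive_euclidean_matrix(X), atol=1e-12)


class TestHierarchical:
    def test_hand_computed_average_linkage_heights(self):
        Z = linkage_tree(distance_matrix(LINE3), "average")
        # {0,1} merge at 1; then {0,1} with {10} at ((10-0)+(10-1))/2 = 9.5
        assert sorted(Z[:, 2]) == pytest.approx([1.0, 9.5])

    def test_degenerate_cuts(self):
        D = distance_matrix(LINE3)
        assert len(np.unique(hierarchical_cluster(D, "average", 3))) == 3
        assert len(np.unique(hierarchical_cluster(D, "average", 1))) == 1

    def test_k_out_of_range(self):
        Z = linkage_tree(distance_matrix(LINE3), "average")
        with pytest.raises(ValueError):
            cut_tree_k(Z, 4)

    def test_tree_matches_bruteforce_upgma_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X = rng.uniform(size=(7, 4))
            D = distance_matrix(X)
            Z = linkage_tree(D, "average")
            from scipy.spatial.distance import squareform

            coph = squareform(hierarchy.cophenet(Z))
            assert np.allclose(coph, naive_average_linkage_cophenetic(D), atol=1e-10)


class TestCophenetic:
    def test_ultrametric_input_is_fixed_point(self):
        # cophenetic distances of any tree are ultrametric; feeding them back
        # reproduces themselves, so the correlation is exactly 1
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(6, 3))
        Z = linkage_tree(distance_matrix(X), "average")
        from scipy.spatial.distance import squareform

        ultra = squareform(hierarchy.cophenet(Z))
        Z2 = linkage_tree(ultra, "average")
        assert cophenetic_correlation(ultra, Z2) == pytest.approx(1.0)

    def test_three_point_hand_computation(self):
        D = distance_matrix(LINE3)
        Z = linkage_tree(D, "average")
        orig = np.array([1.0, 10.0, 9.0])  # condensed (0,1),(0,2),(1,2)
        coph = np.array([1.0, 9.5, 9.5])
        assert cophenetic_correlation(D, Z) == pytest.approx(naive_pearson(orig, coph))

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(9, 5))
        r1 = cophenetic_correlation(distance_matrix(X), linkage_tree(distance_matrix(X)))
        perm = rng.permutation(9)
        Xp = X[perm]
        r2 = cophenetic_correlation(distance_matrix(Xp), linkage_tree(distance_matrix(Xp)))
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_leaves(self):
        D = distance_matrix(np.array([[0.0], [1.0]]))
        with pytest.raises(ArdkitError):
            cophenetic_correlation(D, linkage_tree(D))


class TestSelectLinkage:
    def test_single_candidate(self):
        D = distance_matrix(LINE3)
        best, scores = select_linkage(D, ("average",))
        assert best == "average" and set(scores) == {"average"}

    def test_score_table_covers_all_candidates(self):
        rng = np.random.default_rng(4)
        D = distance_matrix(rng.uniform(size=(10, 6)))
        best, scores = select_linkage(D)
        assert set(scores) == set(LINKAGES)
        assert scores[best] == max(scores.values())

    def test_average_wins_on_standardised_panel(self, panel):
        best, _ = select_linkage(distance_matrix(panel["std"].to_numpy()))
        assert best == "average"


class TestFlatAlgorithms:
    @pytest.mark.parametrize("algo", ["kmeans", "pam", "spectral"])
    def test_perfectly_separated_blobs(self, algo, two_blobs):
        X, truth = two_blobs
        if algo == "kmeans":
            labels = kmeans_cluster(X, 2, seed=0)
        elif algo == "pam":
            labels = pam_cluster(distance_matrix(X), 2)
        else:
            labels = spectral_cluster(X, 2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_pam_three_points_exhaustive(self):
        D = distance_matrix(LINE3)
        labels = pam_cluster(D, 2)
        # optimal medoid pair is {0 or 1, 10} with total cost 1
        medoids_cost = exhaustive_pam(D, 2)
        assert medoids_cost == 1.0
        assert labels[0] == labels[1] != labels[2]

    def test_pam_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(5)
        for n, k in [(8, 2), (9, 3), (10, 3)]:
            X = rng.uniform(size=(n, 3))
            D = distance_matrix(X)
            labels = pam_cluster(D, k)
            # recover medoid set cost from the labels via per-cluster medoid
            cost = 0.0
            for u in np.unique(labels):
                idx = np.flatnonzero(labels == u)
                cost += D[np.ix_(idx, idx)].sum(axis=1).min()
            assert cost == pytest.approx(exhaustive_pam(D, k), abs=1e-10)

    def test_seeded_determinism(self, two_blobs):
        X, _ = two_blobs
        for fn in (lambda: kmeans_cluster(X, 2, seed=7), lambda: spectral_cluster(X, 2, seed=7)):
            assert np.array_equal(fn(), fn())


class TestGapStatistic:
    def test_two_blobs_choose_two(self, two_blobs):
        X, _ = two_blobs
        for reference in ("pca", "box"):
            res = gap_statistic(X, "hierarchical", k_max=6, n_refs=20, seed=0,
                                reference=reference)
            assert res.chosen_k == 2

    def test_wk_matches_pairwise_oracle(self, two_blobs):
        X, labels = two_blobs
        assert within_cluster_dispersion(X, labels) == pytest.approx(
            naive_wk(X, labels), rel=1e-12
        )
        rng = np.random.default_rng(6)
        lab = rng.integers(0, 3, X.shape[0])
        assert within_cluster_dispersion(X, lab) == pytest.approx(naive_wk(X, lab), rel=1e-12)

    def test_kmeans_minimises_w2_over_all_bipartitions(self, two_blobs):
        """At n = 8 the k-means W_2 equals the exhaustive minimum over every
        2-labelling, confirming the gap curve's W values are attainable."""
        full = two_blobs[0]
        X = np.vstack([full[:4], full[10:14]])  # 8 points, 4 per blob
        labels = kmeans_cluster(X, 2, seed=0)
        w = within_cluster_dispersion(X, labels)
        best = np.inf
        for code in range(1, 2**7):  # fix point 0's side to kill symmetry
            lab = np.array([0] + [(code >> i) & 1 for i in range(7)])
            if len(np.unique(lab)) == 2:
                best = min(best, naive_wk(X, lab))
        assert w == pytest.approx(best, rel=1e-10)

    def test_single_reference_draw_is_finite(self, two_blobs):
        X, _ = two_blobs
        res = gap_statistic(X, "kmeans", k_max=4, n_refs=1, seed=1)
        assert np.isfinite(res.gap).all() and np.isfinite(res.s).all()

    def test_structureless_data_prefers_one_cluster(self):
        """Uniform-box data should mostly yield k = 1 (majority over seeds)."""
        votes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(25, 4))
            res = gap_statistic(X, "hierarchical", k_max=5, n_refs=10, seed=seed,
                                reference="box")
            votes.append(res.chosen_k == 1)
        assert sum(votes) > 10


class TestDunn:
    def test_hand_enumeration_two_pairs(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        assert dunn_index(distance_matrix(X), labels) == pytest.approx(9.0)

    def test_zero_diameter_sentinel(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert dunn_index(distance_matrix(X), [0, 0, 1, 1]) == np.inf

    def test_merging_true_blobs_decreases_index(self, two_blobs):
        X, labels = two_blobs
        D = distance_matrix(X)
        good = dunn_index(D, labels)
        rng = np.random.default_rng(8)
        bad_labels = rng.integers(0, 2, X.shape[0])
        assert dunn_index(D, bad_labels) < good

    def test_matches_naive_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.uniform(size=(10, 3))
            labels = rng.integers(0, 3, 10)
            if len(np.unique(labels)) < 2:
                continue
            D = distance_matrix(X)
            assert dunn_index(D, labels) == pytest.approx(naive_dunn(D, labels), rel=1e-12)

    def test_requires_two_clusters(self):
        with pytest.raises(ArdkitError):
            dunn_index(distance_matrix(LINE3), [0, 0, 0])


class TestClustererEstimator:
    def test_selects_hierarchical_on_panel(self, panel):
        X = panel["std"].to_numpy()
        cl = OnsetCurveClusterer(k_max=8, n_refs=10, random_state=0).fit(X)
        assert cl.algorithm_ == "hierarchical"
        assert cl.linkage_ == "average"
        assert cl.dunn_scores_[cl.algorithm_] == max(cl.dunn_scores_.values())
        assert len(np.unique(cl.labels_)) == cl.n_clusters_

    def test_single_candidate_algorithm_is_itself(self, two_blobs):
        X, _ = two_blobs
        cl = OnsetCurveClusterer(algorithms=("pam",), k_max=4, n_refs=5,
                                 random_state=0).fit(X)
        assert cl.algorithm_ == "pam"

    def test_argmax_dunn_selection(self, panel):
        X = panel["std"].to_numpy()
        cl = OnsetCurveClusterer(algorithms=("hierarchical", "kmeans"),
                                 k_max=8, n_refs=5, random_state=0).fit(X)
        better = max(cl.dunn_scores_, key=cl.dunn_scores_.get)
        assert cl.algorithm_ == better

    def test_same_seed_identical_labels(self, two_blobs):
        X, _ = two_blobs
        fits = [
            OnsetCurveClusterer(algorithms=("kmeans",), k_max=4, n_refs=5,
                                random_state=3).fit(X).labels_
            for _ in range(2)
        ]
        assert np.array_equal(fits[0], fits[1])

    def test_input_order_invariance_up_to_relabelling(self, panel):
        X = panel["std"].to_numpy()
        cl = OnsetCurveClusterer(algorithms=("hierarchical",), k_max=8,
                                 n_refs=5, random_state=0).fit(X)
        rng = np.random.default_rng(10)
        perm = rng.permutation(X.shape[0])
        cl2 = OnsetCurveClusterer(algorithms=("hierarchical",), k_max=8,
                                  n_refs=5, random_state=0).fit(X[perm])
        assert adjusted_rand_score(cl.labels_[perm], cl2.labels_) == 1.0


class TestSplitMainOutlier:
    def _medians(self, ids, vals):
        return pd.Series(vals, index=ids)

    def test_size_threshold(self):
        labels = [0] * 5 + [1] * 2 + [2] * 1 + [3] * 4
        ids = [f"d{i}" for i in range(12)]
        med = self._medians(ids, np.linspace(30, 80, 12))
        part = split_main_outlier(labels, ids, med)
        assert part["is_main"].sum() == 9
        assert part.loc[part.is_main, "main_label"].nunique() == 2
        assert part.loc[~part.is_main, "outlier_label"].nunique() == 2

    def test_no_outliers_when_all_large(self):
        labels = [0] * 3 + [1] * 4
        ids = [f"d{i}" for i in range(7)]
        part = split_main_outlier(labels, ids, self._medians(ids, [50] * 7))
        assert part["is_main"].all()

    def test_oldest_onset_cluster_gets_label_one(self):
        labels = [0] * 3 + [1] * 3
        ids = [f"d{i}" for i in range(6)]
        med = self._medians(ids, [30, 31, 32, 80, 81, 82])
        part = split_main_outlier(labels, ids, med)
        # cluster of old-onset diseases (raw label 1) must be main cluster 1
        assert (part.loc[["d3", "d4", "d5"], "main_label"] == 1).all()
        assert (part.loc[["d0", "d1", "d2"], "main_label"] == 2).all()

    def test_every_disease_in_exactly_one_cluster(self, panel):
        X = panel["std"].to_numpy()
        cl = OnsetCurveClusterer(algorithms=("hierarchical",), k_max=8,
                                 n_refs=5, random_state=0).fit(X)
        from ardkit.rates import median_onset_table

        med = median_onset_table(panel["counts"])
        part = split_main_outlier(cl.labels_, panel["std"].index, med["median"])
        assert len(part) == X.shape[0]
        assert (part["is_main"] == part["main_label"].notna()).all()
        assert (part["is_main"] != part["outlier_label"].notna()).all()
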