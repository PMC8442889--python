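"""Agglomeration, linkage quality, dispersion, and gap-statistic selection.

The naive oracle used throughout recomputes all inter-cluster dissimilarities
from scratch at every merge step (O(n^3)), independently of the
Lance-Williams path the implementation takes.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from painclust import hierarchy
from painclust.schema import SYMPTOMS
from painclust.simulate import GeneratorConfig, simulate_baseline


# ---------------------------------------------------------------- oracle ---

def _cluster_dissimilarity(X, a, b, method):
    """Inter-cluster dissimilarity computed from scratch (no recurrence)."""
    pair_d = np.array([np.linalg.norm(X[i] - X[j]) for i in a for j in b])
    if method == "single":
        return pair_d.min()
    if method == "complete":
        return pair_d.max()
    if method == "average":
        return pair_d.mean()
    if method == "ward":
        # distance-scale Ward: sqrt(2 * increase in within-SS) on merging
        ca, cb = X[list(a)].mean(0), X[list(b)].mean(0)
        na, nb = len(a), len(b)
        return np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
    raise ValueError(method)


def naive_agglomerate(X, method):
    """Flat clusterings at every k via from-scratch re-agglomeration."""
    clusters = [frozenset([i]) for i in range(len(X))]
    partitions = {len(clusters): list(clusters)}
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = _cluster_dissimilarity(X, clusters[i], clusters[j], method)
            if best is None or d < best[0] - 1e-12:
                best = (d, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
        partitions[len(clusters)] = list(clusters)
    return partitions


def _partition_signature(labels):
    """Canonical form of a flat clustering, invariant to label names."""
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, []).append(i)
    return frozenset(frozenset(g) for g in groups.values())


# ----------------------------------------------------------------- tests ---

class TestPairwiseDistance:
    def test_identical_rows_and_pythagoras(self):
        D = hierarchy.pairwise_distance(np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == 0.0
        assert D[0, 2] == pytest.approx(5.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 9))
        D = hierarchy.pairwise_distance(X)
        for i in range(20):
            for j in range(20):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-10
                )

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 0.0]])
        with pytest.raises(ValueError):
            hierarchy.pairwise_distance(X)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        D = hierarchy.pairwise_distance(X)
        np.testing.assert_allclose(D, D.T)
        for i, j, k in rng.integers(0, 15, size=(50, 3)):
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-9


class TestAgglomerate:
    def test_single_linkage_first_merge(self):
        tree = hierarchy.agglomerate_points(np.array([0.0, 1.0, 10.0]), "single")
        assert sorted(tree.Z[0, :2]) == [0, 1]
        assert tree.Z[0, 2] == pytest.approx(1.0)

    def test_ward_first_merge_closest_pair(self):
        tree = hierarchy.agglomerate_points(np.array([0.0, 2.0, 10.0]), "ward")
        assert sorted(tree.Z[0, :2]) == [0, 1]
        # distance-scale height: two singletons merge at their distance
        assert tree.Z[0, 2] == pytest.approx(2.0)

    @pytest.mark.parametrize("method", ["single", "complete", "average", "ward"])
    def test_flat_clusterings_match_naive_oracle(self, method):
        rng = np.random.default_rng(17)
        for trial in range(3):
            X = rng.normal(size=(8, 3))
            tree = hierarchy.agglomerate_points(X, method)
            oracle = naive_agglomerate(X, method)
            for k in range(1, 9):
                got = _partition_signature(hierarchy.cut_tree(tree, k))
                want = frozenset(oracle[k])
                assert got == want, f"{method}, trial {trial}, k={k}"

    def test_ward_heights_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 9))
        tree = hierarchy.agglomerate_points(X, "ward")
        assert (np.diff(tree.heights()) >= -1e-12).all()

    def test_ward_d_variant_runs_and_is_monotone_here(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        tree = hierarchy.agglomerate(hierarchy.pairwise_distance(X), "ward.D")
        assert tree.Z.shape == (11, 4)
        assert tree.method == "ward.D"

    def test_newick_export_parses(self):
        tree = hierarchy.agglomerate_points(np.array([0.0, 1.0, 10.0]), "average")
        text = tree.to_newick(["a", "b", "c"])
        assert text.endswith(";") and text.count("(") == 2


class TestAgglomerativeCoefficient:
    def test_two_points_is_zero(self):
        tree = hierarchy.agglomerate_points(np.array([0.0, 5.0]), "average")
        assert hierarchy.agglomerative_coefficient(tree) == pytest.approx(0.0)

    def test_hand_evaluated_triple(self):
        # {0, 1, 100}, average linkage: first merges at 1, 1, 99.5
        tree = hierarchy.agglomerate_points(np.array([0.0, 1.0, 100.0]), "average")
        expected = (2 * (1 - 1 / 99.5) + 0.0) / 3
        assert hierarchy.agglomerative_coefficient(tree) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.6600, abs=5e-4)

    def test_tends_to_one_with_separation(self):
        rng = np.random.default_rng(1)
        blobs = lambda sep: np.concatenate(
            [rng.normal(c * sep, 0.1, size=20) for c in range(3)]
        )
        ac = [
            hierarchy.agglomerative_coefficient(
                hierarchy.agglomerate_points(blobs(sep), "average")
            )
            for sep in (2.0, 20.0, 200.0)
        ]
        assert ac[0] < ac[1] < ac[2] < 1.0
        assert ac[2] > 0.99

    def test_identical_points_signalled(self):
        tree = hierarchy.agglomerate_points(np.zeros(4), "average")
        with pytest.raises(ValueError):
            hierarchy.agglomerative_coefficient(tree)


class TestCutTree:
    def test_extremes(self):
        rng = np.random.default_rng(4)
        tree = hierarchy.agglomerate_points(rng.normal(size=(7, 2)), "ward")
        assert len(set(hierarchy.cut_tree(tree, 1))) == 1
        assert len(set(hierarchy.cut_tree(tree, 7))) == 7

    def test_three_cluster_cut_on_constructed_points(self):
        # three tight 1-D blobs: cut at k=3 must recover them
        X = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2, 50.0, 50.1, 50.2])
        tree = hierarchy.agglomerate_points(X, "ward")
        labels = hierarchy.cut_tree(tree, 3)
        assert _partition_signature(labels) == _partition_signature(
            [0, 0, 0, 1, 1, 1, 2, 2, 2]
        )

    def test_out_of_range_k(self):
        tree = hierarchy.agglomerate_points(np.arange(5.0), "ward")
        with pytest.raises(ValueError):
            hierarchy.cut_tree(tree, 6)


class TestWithinDispersion:
    def test_singletons_zero(self):
        X = np.arange(6.0).reshape(3, 2)
        assert hierarchy.within_dispersion(X, [1, 2, 3]) == 0.0

    def test_two_point_cluster(self):
        # {0, 2} in 1-D: ordered-pair form (2^2 + 2^2)/(2*2) = 2, which equals
        # the within-SS about the centroid (1 + 1)
        assert hierarchy.within_dispersion(np.array([0.0, 2.0]), [1, 1]) == pytest.approx(2.0)

    def test_pairwise_form_equals_centroid_form(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 9))
        labels = rng.integers(1, 4, size=30)
        pairwise = 0.0
        for l in np.unique(labels):
            sub = X[labels == l]
            d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
            pairwise += d2.sum() / (2 * len(sub))
        assert hierarchy.within_dispersion(X, labels) == pytest.approx(
            pairwise, abs=1e-9
        )


class TestGapStatistic:
    def test_separated_blobs_select_three(self, table_means):
        rng = np.random.default_rng(21)
        X = np.vstack(
            [rng.normal(m, 1.0, size=(50, 9)) for m in table_means.to_numpy()]
        )
        curve = hierarchy.gap_statistic(X, kmax=6, B=20, seed=0)
        assert hierarchy.select_k(curve) == 3

    def test_single_blob_selects_one(self):
        rng = np.random.default_rng(22)
        X = rng.uniform(0, 1, size=(120, 4))
        curve = hierarchy.gap_statistic(X, kmax=6, B=20, seed=1)
        assert hierarchy.select_k(curve) == 1

    def test_requires_two_reference_sets(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError):
            hierarchy.gap_statistic(X, kmax=3, B=1)

    def test_kmax_bounded_by_n(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            hierarchy.gap_statistic(X, kmax=5, B=5)

    def test_pca_reference_runs(self):
        X = np.random.default_rng(7).normal(size=(60, 3))
        curve = hierarchy.gap_statistic(X, kmax=4, B=5, reference="pca", seed=2)
        assert curve.kmax == 4 and (curve.se > 0).all()


class TestSelectK:
    def test_one_se_rule_arithmetic(self):
        curve = hierarchy.GapCurve(
            gap=np.array([1.0, 5.0, 5.1]),
            se=np.array([0.1, 0.1, 0.2]),
            log_wk=np.zeros(3), ref_log_wk=np.zeros(3), n_reference=10,
        )
        assert hierarchy.select_k(curve) == 2

    def test_monotone_gap_with_tiny_se_selects_max(self):
        curve = hierarchy.GapCurve(
            gap=np.array([1.0, 2.0, 3.0]),
            se=np.full(3, 1e-6),
            log_wk=np.zeros(3), ref_log_wk=np.zeros(3), n_reference=10,
        )
        assert hierarchy.select_k(curve) == 3

    def test_flat_curve_selects_one(self):
        curve = hierarchy.GapCurve(
            gap=np.array([1.0, 1.01, 1.02]),
            se=np.full(3, 0.5),
            log_wk=np.zeros(3), ref_log_wk=np.zeros(3), n_reference=10,
        )
        assert hierarchy.select_k(curve) == 1

    def test_sequential_variant(self):
        curve = hierarchy.GapCurve(
            gap=np.array([1.0, 5.0, 5.05]),
            se=np.array([0.1, 0.1, 0.1]),
            log_wk=np.zeros(3), ref_log_wk=np.zeros(3), n_reference=10,
        )
        assert hierarchy.select_k(curve, rule="first-se") == 2


class TestFitModel:
    def test_severity_labels_ordered(self, clean_cohort):
        X = clean_cohort.cohort.data[list(SYMPTOMS)]
        model = hierarchy.fit_model(X, 3)
        from painclust.separability import norm_deviation

        dev = norm_deviation(model.centroids).deviation
        assert dev.is_monotonic_increasing

    def test_centroid_recovery_on_clean_mixture(self, clean_cohort, table_means):
        X = clean_cohort.cohort.data[list(SYMPTOMS)]
        model = hierarchy.fit_model(X, 3)
        np.testing.assert_allclose(
            model.centroids.to_numpy(), table_means.to_numpy(), atol=1.0
        )

    def test_labels_invariant_to_row_permutation(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(
            np.vstack([rng.normal(c * 30, 1, size=(20, 9)) for c in range(3)]),
            columns=list(SYMPTOMS),
        )
        model = hierarchy.fit_model(X, 3)
        perm = rng.permutation(len(X))
        model_p = hierarchy.fit_model(X.iloc[perm].reset_index(drop=True), 3)
        assert np.array_equal(model.labels[perm], model_p.labels)

    def test_centroids_are_exact_member_means(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(50, 10, size=(30, 9)), columns=list(SYMPTOMS))
        model = hierarchy.fit_model(X, 4)
        for c in model.centroids.index:
            np.testing.assert_allclose(
                model.centroids.loc[c].to_numpy(),
                X[model.labels == c].mean().to_numpy(),
                atol=1e-12,
            )

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(50, 10, size=(20, 9)), columns=list(SYMPTOMS))
        model = hierarchy.fit_model(X, 2, seed=3)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = hierarchy.ClusterModel.from_json(path)
        assert loaded.k == 2 and loaded.linkage == "ward" and loaded.seed == 3
        np.testing.assert_allclose(
            loaded.centroids.to_numpy(), model.centroids.to_numpy()
        )
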