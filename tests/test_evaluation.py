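"""Evaluation statistics against hand-computed values and independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from oracles import brute_ndcg, brute_spearman

from annsim import (
    EvaluationError,
    category_score,
    correlation,
    coupling,
    davies_bouldin,
    fisher_z_statistic,
    fisher_z_test,
    jaccard_clustering,
    jaccard_set,
    ndcg,
)


class TestNdcg:
    def test_perfect_ranking_is_one(self):
        items = ["a", "b", "c"]
        assert ndcg(items, [0.9, 0.5, 0.1], [3.0, 2.0, 1.0]) == pytest.approx(1.0)

    def test_hand_computed_permutation(self):
        # relevance (3,2,1) ranked by scores as (1,3,2):
        # DCG = 1 + 3/1 + 2/log2(3); ideal = 3 + 2 + 1/log2(3).
        items = ["a", "b", "c"]  # rel 3, 2, 1
        scores = [0.1, 0.5, 0.9]  # ranking: c (rel 1), b (rel 2)... recheck below
        # ranking by descending score: c, b, a -> rel order (1, 2, 3)
        got = ndcg(items, scores, [3.0, 2.0, 1.0])
        expected = (1 + 2 / 1 + 3 / math.log2(3)) / (3 + 2 / 1 + 1 / math.log2(3))
        assert got == pytest.approx(expected)

    def test_specific_dcg_form(self):
        # score order places rel sequence (1, 3, 2)
        items = ["a", "b", "c"]  # rel 3, 2, 1
        scores = [0.5, 0.1, 0.9]  # ranking: c (1), a (3), b (2)
        got = ndcg(items, scores, [3.0, 2.0, 1.0])
        expected = (1 + 3 / 1 + 2 / math.log2(3)) / (3 + 2 / 1 + 1 / math.log2(3))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.9345, abs=5e-4)

    def test_single_item(self):
        assert ndcg(["a"], [0.3], [2.0]) == pytest.approx(1.0)

    def test_all_zero_relevance_errors(self):
        with pytest.raises(EvaluationError):
            ndcg(["a", "b"], [1.0, 0.5], [0.0, 0.0])

    def test_tie_handling_is_permutation_invariant(self, rng):
        items = [f"i{k}" for k in range(8)]
        scores = [0.5] * 4 + [0.9] * 4  # heavy ties
        relevance = list(rng.integers(1, 5, size=8).astype(float))
        base = ndcg(items, scores, relevance)
        perm = rng.permutation(8)
        got = ndcg([items[i] for i in perm], [scores[i] for i in perm],
                   [relevance[i] for i in perm])
        assert got == pytest.approx(base)

    def test_matches_independent_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            items = [f"i{k}" for k in range(n)]
            scores = list(rng.random(n))
            relevance = list(rng.integers(0, 5, size=n).astype(float))
            if all(r == 0 for r in relevance):
                relevance[0] = 1.0
            assert ndcg(items, scores, relevance) == pytest.approx(
                brute_ndcg(items, scores, relevance))

    def test_exponential_gain_variant(self):
        # high-relevance item demoted to rank 3, where the discount bites:
        # the 2^r - 1 gain punishes the misranking harder than linear gain
        items = ["a", "b", "c"]  # rel 3, 1, 0
        scores = [0.1, 0.9, 0.5]  # ranking: b, c, a
        linear = ndcg(items, scores, [3.0, 1.0, 0.0])
        expo = ndcg(items, scores, [3.0, 1.0, 0.0], exponential=True)
        assert expo < linear < 1.0


class TestCorrelation:
    def test_perfect_and_anti(self):
        x = [1.0, 2.0, 3.0, 4.0]
        for method in ("pearson", "spearman"):
            assert correlation(x, x, method) == pytest.approx(1.0)
            assert correlation(x, [-v for v in x], method) == pytest.approx(-1.0)

    def test_spearman_hand_value(self):
        assert correlation([1, 2, 3, 4], [2, 1, 4, 3], "spearman") == pytest.approx(0.6)

    def test_spearman_midranks_match_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 20))
            x = list(rng.integers(0, 5, size=n).astype(float))
            y = list(rng.integers(0, 5, size=n).astype(float))
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert correlation(x, y, "spearman") == pytest.approx(
                brute_spearman(x, y))

    def test_pearson_affine_invariance(self, rng):
        x = list(rng.random(10))
        y = list(rng.random(10))
        r = correlation(x, y, "pearson")
        assert correlation([3 * v + 7 for v in x], y, "pearson") == pytest.approx(r)

    def test_degenerate_inputs(self):
        with pytest.raises(EvaluationError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(EvaluationError):
            correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(EvaluationError):
            correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="kendall")


class TestFisherZ:
    def test_equal_correlations_p_one(self):
        assert fisher_z_test(0.4, 0.4, 100) == pytest.approx(1.0)

    def test_closed_form_statistic(self):
        assert fisher_z_statistic(0.5, 0.0, 103) == pytest.approx(
            math.atanh(0.5) * 10)
        assert fisher_z_statistic(0.5, 0.0, 103) == pytest.approx(5.493, abs=5e-4)

    def test_large_sample_separated_correlations_significant(self):
        # the regime of comparing a strong vs a weak measure correlation
        assert fisher_z_test(0.6510, 0.2164, 1000) < 0.01

    def test_bounds(self):
        with pytest.raises(EvaluationError):
            fisher_z_test(1.0, 0.0, 100)
        with pytest.raises(EvaluationError):
            fisher_z_test(0.5, 0.0, 3)


class TestJaccard:
    def test_values(self):
        assert jaccard_set({1, 2, 3}, {1, 2, 3}) == 1.0
        assert jaccard_set({1}, {2}) == 0.0
        assert jaccard_set({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_error(self):
        with pytest.raises(EvaluationError):
            jaccard_set(set(), set())


class TestCategoryScore:
    def test_identical_sets_grouping_scores_one(self):
        C = {"a": "k1", "b": "k1", "c": "k2", "d": "k3"}
        cats = {"a": {"x", "y"}, "b": {"x", "y"}, "c": {"z"}, "d": {"x"}}
        assert category_score(C, cats) == 1.0

    def test_disjoint_pair_scores_zero(self):
        C = {"a": "k1", "b": "k1"}
        cats = {"a": {"x"}, "b": {"y"}}
        assert category_score(C, cats) == 0.0

    def test_pooled_pair_mean(self):
        C = {"a": "k1", "b": "k1", "c": "k2", "d": "k2"}
        cats = {"a": {"x"}, "b": {"x"}, "c": {"x", "y"}, "d": {"x", "z"}}
        # pairs: (a,b) -> 1.0 and (c,d) -> 1/3
        assert category_score(C, cats) == pytest.approx((1.0 + 1 / 3) / 2)

    def test_singletons_contribute_no_pairs(self):
        C = {"a": "k1", "b": "k2"}
        with pytest.raises(EvaluationError):
            category_score(C, {"a": {"x"}, "b": {"y"}})


class TestJaccardClustering:
    def test_identity(self):
        C = {"a": "1", "b": "1", "c": "2"}
        assert jaccard_clustering(C, C) == 1.0

    def test_split_cluster_pair_counts(self):
        # one big cluster of 4 vs two clusters of 2: n11=2, n10=4, n01=0
        C1 = {e: "all" for e in "abcd"}
        C2 = {"a": "1", "b": "1", "c": "2", "d": "2"}
        assert jaccard_clustering(C1, C2) == pytest.approx(1 / 3)

    def test_all_singletons_vacuous_case(self):
        C = {e: e for e in "abc"}
        assert jaccard_clustering(C, dict(C)) == 1.0

    def test_symmetry_and_comembership_characterisation(self, rng):
        entities = [f"e{i}" for i in range(10)]
        for _ in range(10):
            C1 = {e: str(rng.integers(0, 4)) for e in entities}
            C2 = {e: str(rng.integers(0, 4)) for e in entities}
            assert jaccard_clustering(C1, C2) == jaccard_clustering(C2, C1)
        relabelled = {e: "x" + C1[e] for e in entities}  # same partition
        assert jaccard_clustering(C1, relabelled) == 1.0

    def test_mismatched_universes(self):
        with pytest.raises(EvaluationError):
            jaccard_clustering({"a": "1"}, {"b": "1"})


class TestDaviesBouldin:
    @pytest.fixture
    def two_flat_clusters(self):
        F = pd.DataFrame(
            [[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]],
            index=["a", "b", "c", "d"],
        )
        C = {"a": "1", "b": "1", "c": "2", "d": "2"}
        return F, C

    def test_singleton_clusters_zero(self):
        F = pd.DataFrame([[0.0, 0.0], [5.0, 5.0]], index=["a", "b"])
        C = {"a": "1", "b": "2"}
        for variant in ("printed", "standard"):
            assert davies_bouldin(F, C, variant) == 0.0

    def test_standard_variant_hand_geometry(self, two_flat_clusters):
        F, C = two_flat_clusters
        # d1 = d2 = 1, centroid distance 10 -> (1+1)/10 = 0.2
        assert davies_bouldin(F, C, "standard") == pytest.approx(0.2)

    def test_printed_variant_hand_geometry(self, two_flat_clusters):
        F, C = two_flat_clusters
        # d_12 = mean distance of cluster-1 points to centroid 2 = sqrt(101)
        assert davies_bouldin(F, C, "printed") == pytest.approx(2 / math.sqrt(101))

    def test_standard_variant_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(5):
            X = rng.normal(size=(20, 3))
            labels = rng.integers(0, 3, size=20)
            if len(set(labels.tolist())) < 2:
                continue
            F = pd.DataFrame(X, index=[f"e{i}" for i in range(20)])
            C = {f"e{i}": str(l) for i, l in enumerate(labels)}
            assert davies_bouldin(F, C, "standard") == pytest.approx(
                float(sklearn_metrics.davies_bouldin_score(X, labels)))

    def test_translation_apart_decreases_standard_index(self, rng):
        X = rng.normal(size=(10, 2))
        F1 = pd.DataFrame(np.vstack([X, X + 5.0]),
                          index=[f"e{i}" for i in range(20)])
        F2 = pd.DataFrame(np.vstack([X, X + 50.0]),
                          index=[f"e{i}" for i in range(20)])
        C = {f"e{i}": ("1" if i < 10 else "2") for i in range(20)}
        assert davies_bouldin(F2, C, "standard") < davies_bouldin(F1, C, "standard")

    def test_coincident_centroids_error(self):
        F = pd.DataFrame([[0.0, 0.0], [2.0, 0.0], [0.0, 0.0], [2.0, 0.0]],
                         index=["a", "b", "c", "d"])
        C = {"a": "1", "b": "1", "c": "2", "d": "2"}
        with pytest.raises(EvaluationError, match="degenerate"):
            davies_bouldin(F, C, "standard")

    def test_single_cluster_error(self):
        F = pd.DataFrame([[0.0], [1.0]], index=["a", "b"])
        with pytest.raises(EvaluationError):
            davies_bouldin(F, {"a": "1", "b": "1"})


class TestCoupling:
    def test_identical_centroids(self):
        F = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"])
        assert coupling(F, {"a": "1", "b": "2"}) == pytest.approx(1.0)

    def test_orthogonal_centroids(self):
        F = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert coupling(F, {"a": "1", "b": "2"}) == pytest.approx(0.0)

    def test_three_centroid_hand_value(self):
        F = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]],
                         index=["a", "b", "c"])
        C = {"a": "1", "b": "2", "c": "3"}
        expected = (0.0 + 1 / math.sqrt(2) + 1 / math.sqrt(2)) / 3
        assert coupling(F, C) == pytest.approx(expected)
        assert coupling(F, C) == pytest.approx(0.4714, abs=5e-4)

    def test_zero_norm_centroid_error(self):
        F = pd.DataFrame([[0.0, 0.0], [1.0, 0.0]], index=["a", "b"])
        with pytest.raises(EvaluationError):
            coupling(F, {"a": "1", "b": "2"})
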