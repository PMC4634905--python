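"""Evaluation metrics vs. hand-worked examples, brute-force oracles and scikit-learn."""

import numpy as np
import pytest
from sklearn.metrics import (
    average_precision_score,
    coverage_error,
    label_ranking_loss,
    roc_auc_score,
)

from fsmlknn import (
    UndefinedMetricError,
    ValidationError,
    compare_methods,
    hamming_loss,
    micro_aupr,
    micro_auc,
    per_label_aupr,
    ranking_metrics,
    topn_recall,
)
from oracles import (
    brute_aupr,
    brute_auc,
    brute_hamming,
    brute_ranking_metrics,
    brute_topn_recall,
)


def random_instance(rng, n=6, q=5, tie_prone=True):
    # coarse score grid makes ties frequent, exercising tie conventions
    grid = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], (n, q)) if tie_prone else rng.random((n, q))
    Y = rng.integers(0, 2, (n, q))
    return grid, Y


class TestMicroAupr:
    def test_worked_example(self):
        # positives at ranks 1 and 3: (1/2)(1/1 + 2/3)
        assert micro_aupr(np.array([[0.9, 0.8, 0.3, 0.1]]), np.array([[1, 0, 1, 0]])) == pytest.approx(
            0.833333333, abs=1e-9
        )

    def test_perfect_ranking(self):
        assert micro_aupr(np.array([[0.9, 0.8, 0.3, 0.1]]), np.array([[1, 1, 0, 0]])) == 1.0

    def test_all_positive(self):
        assert micro_aupr(np.array([[0.2, 0.5]]), np.array([[1, 1]])) == 1.0

    def test_zero_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            micro_aupr(np.array([[0.2, 0.5]]), np.array([[0, 0]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        S, Y = random_instance(rng)
        if Y.sum() == 0:
            Y[0, 0] = 1
        got = micro_aupr(S, Y)
        assert got == pytest.approx(brute_aupr(S, Y), abs=1e-12)
        assert got == pytest.approx(average_precision_score(Y.ravel(), S.ravel()), abs=1e-12)

    def test_random_ranking_concentrates_near_prevalence(self):
        # stochastic: mean AUPR of random score permutations ~ positive prevalence
        rng = np.random.default_rng(0)
        y = np.zeros(200, dtype=int)
        y[:40] = 1  # prevalence 0.2
        vals = []
        for _ in range(100):
            s = rng.permutation(np.linspace(0, 1, 200))
            vals.append(micro_aupr(s[None, :], y[None, :]))
        assert abs(np.mean(vals) - 0.2) < 0.03


class TestMicroAuc:
    def test_perfect_separation(self):
        assert micro_auc(np.array([[0.9, 0.8, 0.3]]), np.array([[1, 1, 0]])) == 1.0

    def test_constant_scores_give_half(self):
        assert micro_auc(np.full((1, 4), 0.5), np.array([[1, 0, 1, 0]])) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            micro_auc(np.array([[0.2, 0.5]]), np.array([[1, 1]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_concordant_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        S, Y = random_instance(rng, n=4, q=5)
        if Y.sum() in (0, Y.size):
            Y[0, 0] = 1 - Y[0, 0]
        got = micro_auc(S, Y)
        assert got == pytest.approx(brute_auc(S, Y), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(Y.ravel(), S.ravel()), abs=1e-12)


class TestRankingMetrics:
    def test_single_instance_worked_example(self):
        one_error, coverage, rloss, ap = ranking_metrics(np.array([[0.9, 0.1]]), np.array([[0, 1]]))
        assert (one_error, rloss, coverage, ap) == (1.0, 1.0, 1.0, 0.5)

    def test_coverage_counts_steps_to_deepest_relevant(self):
        _, coverage, _, _ = ranking_metrics(np.array([[0.9, 0.5, 0.1]]), np.array([[0, 0, 1]]))
        assert coverage == 2.0

    def test_perfectly_ranked_instance(self):
        one_error, coverage, rloss, ap = ranking_metrics(
            np.array([[0.9, 0.8, 0.1, 0.05]]), np.array([[1, 1, 0, 0]])
        )
        assert (one_error, rloss, ap) == (0.0, 0.0, 1.0)
        assert coverage == 1.0  # = number of relevant labels - 1

    def test_no_relevant_labels_skipped_but_coverage_zero(self):
        one_error, coverage, rloss, ap = ranking_metrics(
            np.array([[0.9, 0.1], [0.3, 0.6]]), np.array([[0, 0], [1, 0]])
        )
        # first instance contributes 0; second's relevant label sits at rank 2
        assert coverage == pytest.approx((0.0 + 1.0) / 2)
        assert one_error == 1.0  # only the second instance counts

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        S, Y = random_instance(rng, n=7, q=6)
        got = ranking_metrics(S, Y)
        want = brute_ranking_metrics(S, Y)
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_sklearn_on_clean_instances(self):
        # rows with >= 1 relevant and >= 1 irrelevant label, untied scores
        rng = np.random.default_rng(3)
        S = rng.random((8, 6))
        Y = rng.integers(0, 2, (8, 6))
        Y[:, 0], Y[:, 1] = 1, 0
        _, coverage, rloss, _ = ranking_metrics(S, Y)
        assert rloss == pytest.approx(label_ranking_loss(Y, S), abs=1e-12)
        assert coverage == pytest.approx(coverage_error(Y, S) - 1, abs=1e-12)


class TestHammingLoss:
    def test_total_disagreement(self):
        assert hamming_loss(np.array([[1, 0]]), np.array([[0, 1]])) == 1.0

    def test_agreement(self):
        Y = np.array([[1, 0], [0, 1]])
        assert hamming_loss(Y, Y) == 0.0

    def test_matches_direct_count(self, rng):
        P = rng.integers(0, 2, (5, 4))
        Y = rng.integers(0, 2, (5, 4))
        assert hamming_loss(P, Y) == pytest.approx(brute_hamming(P, Y), abs=1e-15)


class TestPerLabelAupr:
    def test_zero_positive_label_undefined(self):
        S = np.array([[0.9, 0.1], [0.2, 0.8]])
        Y = np.array([[1, 0], [0, 0]])
        vals = per_label_aupr(S, Y)
        assert vals[0] == 1.0
        assert np.isnan(vals[1])

    def test_defined_count(self, rng):
        S = rng.random((6, 5))
        Y = rng.integers(0, 2, (6, 5))
        Y[:, 2] = 0
        vals = per_label_aupr(S, Y)
        assert np.isnan(vals).sum() == (Y.sum(axis=0) == 0).sum()


class TestCompareMethods:
    def test_three_way_counts(self):
        a = np.array([0.5, 0.5, 0.9])
        b = np.array([0.4, 0.5, 1.0])
        assert compare_methods(a, b) == (1, 1, 1)

    def test_identical_vectors(self):
        a = np.array([0.1, 0.2, np.nan])
        assert compare_methods(a, a.copy()) == (0, 2, 0)

    def test_counts_sum_to_defined_labels(self, rng):
        a, b = rng.random(20), rng.random(20)
        a[3] = b[3] = np.nan
        assert sum(compare_methods(a, b)) == 19

    def test_mismatched_definition_sets_rejected(self):
        with pytest.raises(ValidationError):
            compare_methods(np.array([0.1, np.nan]), np.array([np.nan, 0.1]))


class TestTopnRecall:
    def test_partial_recall(self):
        S = np.array([[0.9, 0.8, 0.7, 0.6, 0.1, 0.05]])
        Y = np.array([[1, 1, 0, 1, 0, 1]])  # 4 relevant, 3 inside top-4
        per_drug, mean = topn_recall(S, Y, 4)
        assert per_drug[0] == pytest.approx(0.75)

    def test_full_width_recall_is_one(self, rng):
        S = rng.random((5, 6))
        Y = rng.integers(0, 2, (5, 6))
        Y[0] = 0
        per_drug, _ = topn_recall(S, Y, 6)
        assert np.isnan(per_drug[0])
        assert np.all(per_drug[1:][Y[1:].sum(axis=1) > 0] == 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_set_intersection(self, seed):
        rng = np.random.default_rng(seed)
        S, Y = random_instance(rng, n=6, q=8)
        per_drug, mean = topn_recall(S, Y, 3)
        want_per, want_mean = brute_topn_recall(S, Y, 3)
        np.testing.assert_allclose(per_drug, want_per, atol=1e-12)
        if not np.isnan(mean):
            assert mean == pytest.approx(want_mean, abs=1e-12)
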