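"""Mutual-information filter, GA wrapper, and the five-submodel FS-MLKNN assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from fsmlknn import (
    ConfigurationError,
    FeatureTable,
    GAConfig,
    LabelTable,
    MLKNNConfig,
    ValidationError,
    dim_frequency,
    fit_fs_mlknn,
    ga_select_dims,
    mi_filter,
    mutual_information,
    predict_fs_mlknn,
    predict_scores,
)
from fsmlknn.synthetic import FeatureSpec, SyntheticSpec, generate
from conftest import random_tables
from oracles import brute_mi_bits

FAST_GA = GAConfig(population_size=20, max_generations=15, seed=0)


class TestMutualInformation:
    def test_perfectly_dependent_balanced_pair_is_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_empirically_independent_pair_is_zero(self):
        assert mutual_information([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information([0, 1], [0, 1, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_contingency_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 20)
        y = rng.integers(0, 2, 20)
        got = mutual_information(x, y)
        assert got == pytest.approx(brute_mi_bits(x, y), abs=1e-12)
        assert got == pytest.approx(mutual_info_score(x, y) / np.log(2), abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(0, 1), min_size=2, max_size=30),
        bits=st.data(),
    )
    def test_property_symmetry_and_oracle(self, x, bits):
        y = bits.draw(st.lists(st.integers(0, 1), min_size=len(x), max_size=len(x)))
        mi = mutual_information(x, y)
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-15)
        assert mi >= 0
        assert mi == pytest.approx(brute_mi_bits(x, y), abs=1e-12)

    def test_symmetric_nonnegative_bounded_by_entropy(self, rng):
        for _ in range(10):
            x = rng.integers(0, 2, 15)
            y = rng.integers(0, 2, 15)
            mi = mutual_information(x, y)
            assert mi == pytest.approx(mutual_information(y, x), abs=1e-15)
            assert mi >= 0

            def h(v):
                p = v.mean()
                return 0.0 if p in (0, 1) else -p * np.log2(p) - (1 - p) * np.log2(1 - p)

            assert mi <= min(h(x), h(y)) + 1e-12


class TestMiFilter:
    def test_threshold_is_strict_and_max_aggregated(self):
        # dim0 mirrors label0 exactly (1 bit); dim1 is constant (score 0)
        X = np.array([[1, 0], [1, 0], [0, 0], [0, 0]])
        Y = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
        ft = FeatureTable(list("ABCD"), ["d0", "d1"], X, "f")
        lt = LabelTable(list("ABCD"), ["s0", "s1"], Y)
        mi = mi_filter(ft, lt, sigma=0.001)
        assert mi.selected == ["d0"]
        assert mi.scores[0] == pytest.approx(1.0)
        # max over labels: dim0's score comes from its best label
        assert mi.scores[0] == max(
            mutual_information(X[:, 0], Y[:, 0]), mutual_information(X[:, 0], Y[:, 1])
        )

    def test_empty_selection_falls_back_to_top_tenth(self):
        X = np.zeros((6, 20), dtype=int)  # constant dims: all scores 0
        Y = np.array([[1], [0], [1], [0], [1], [0]])
        ft = FeatureTable([f"d{i}" for i in range(6)], [f"v{j}" for j in range(20)], X, "f")
        lt = LabelTable(ft.drug_ids, ["s0"], Y)
        mi = mi_filter(ft, lt, sigma=0.001)
        assert mi.fallback_used
        assert len(mi.selected) == 2  # ceil(20/10)

    def test_noise_dims_rejected_once_bias_is_below_sigma(self):
        """At n=10000 the plug-in MI bias ~1/(2 n ln 2) is far below 0.001, so
        pure-noise dims fall under the threshold while planted dims survive."""
        spec = SyntheticSpec(
            n_drugs=10000,
            feature_specs=(FeatureSpec("f", p=50, n_informative=5),),
            seed=11,
        )
        b = generate(spec)
        mi = mi_filter(b.features["f"], b.labels, sigma=0.001)
        planted = set(b.ground_truth["planted_dims"]["f"])
        assert planted <= set(mi.selected)
        noise = set(b.features["f"].dim_ids) - planted
        rejected = noise - set(mi.selected)
        assert len(rejected) >= 0.5 * len(noise)


class TestGASelect:
    def test_single_candidate_dim_is_chosen(self, rng):
        ft, lt = random_tables(rng, n=12, p=1, q=2)
        chosen, result = ga_select_dims(ft, lt, FAST_GA, MLKNNConfig(k=2), seed=0)
        assert chosen == ft.dim_ids

    def test_fitness_trace_non_decreasing(self, rng):
        ft, lt = random_tables(rng, n=15, p=6, q=3)
        _, result = ga_select_dims(ft, lt, FAST_GA, MLKNNConfig(k=2), seed=1)
        assert all(b >= a for a, b in zip(result.trace, result.trace[1:]))


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(
        n_drugs=80,
        feature_specs=(FeatureSpec("f", p=12, n_informative=3),),
        q_labels=10,
        seed=5,
    )
    b = generate(spec)
    model = fit_fs_mlknn(b.features["f"], b.labels, ga=FAST_GA, mlknn=MLKNNConfig(k=3), seed=5)
    return b, model


class TestFitFsMlknn:
    def test_exactly_five_submodels(self, planted):
        _, model = planted
        assert len(model.submodels) == 5

    def test_chosen_dims_within_mi_selection(self, planted):
        _, model = planted
        assert set(model.chosen_dims) <= set(model.candidate_dims)

    def test_submodels_trained_on_fold_complements(self, planted):
        b, model = planted
        sizes = [m.train_features.shape[0] for m in model.submodels]
        n = b.labels.n_drugs
        fold_sizes = np.bincount(model.fold_assignment, minlength=5)
        assert sizes == [n - fs for fs in fold_sizes]

    def test_too_few_drugs_rejected(self, rng):
        ft, lt = random_tables(rng, n=8, p=4, q=2)
        with pytest.raises(ConfigurationError):
            fit_fs_mlknn(ft, lt, ga=FAST_GA, mlknn=MLKNNConfig(k=1), seed=0)

    def test_reproducible_given_seed(self, rng):
        ft, lt = random_tables(rng, n=30, p=6, q=3)
        a = fit_fs_mlknn(ft, lt, ga=FAST_GA, mlknn=MLKNNConfig(k=2), seed=9)
        b = fit_fs_mlknn(ft, lt, ga=FAST_GA, mlknn=MLKNNConfig(k=2), seed=9)
        assert a.chosen_dims == b.chosen_dims
        assert a.fitness_trace == b.fitness_trace
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_prediction_is_mean_of_submodels(self, planted):
        b, model = planted
        query = b.features["f"]
        got = predict_fs_mlknn(model, query).scores
        sub_q = query.restrict_dims(model.chosen_dims)
        manual = np.zeros_like(got)
        for m in model.submodels:
            manual += predict_scores(m, sub_q).scores
        manual /= len(model.submodels)
        np.testing.assert_allclose(got, manual, atol=1e-15)

    def test_missing_query_dims_rejected(self, planted):
        _, model = planted
        bad = FeatureTable(["x"], ["nothere"], np.array([[1]]), "f")
        with pytest.raises(ValidationError):
            predict_fs_mlknn(model, bad)


class TestDimFrequency:
    def _model_with_dims(self, rng, dims, all_dims):
        ft, lt = random_tables(rng, n=30, p=len(all_dims), q=2)
        ft = FeatureTable(ft.drug_ids, all_dims, ft.values, "f")
        model = fit_fs_mlknn(ft, lt, ga=FAST_GA, mlknn=MLKNNConfig(k=2), seed=1)
        model.chosen_dims = dims
        return model

    def test_counts_and_identity(self, rng):
        all_dims = [f"v{j}" for j in range(4)]
        models = [
            self._model_with_dims(rng, ["v0", "v1"], all_dims),
            self._model_with_dims(rng, ["v0"], all_dims),
            self._model_with_dims(rng, ["v0", "v3"], all_dims),
        ]
        freq, per_model = dim_frequency(models)
        assert freq == {"v0": 3, "v1": 1, "v3": 1}
        assert per_model == [2, 1, 2]
        assert max(freq.values()) <= len(models)
        # per-model chosen count equals the sum of that model's indicators
        assert sum(per_model) == sum(freq.values())
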