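"""AutoML engine: decoding, fitness, search contracts."""

import numpy as np
import pandas as pd
import pytest

from ppcml import automl, cohort


@pytest.fixture(scope="module")
def space():
    return automl.default_space(n_estimators=15)


@pytest.fixture(scope="module")
def tiny_train():
    """Small training table with clear signal, cheap to cross-validate."""
    df = cohort.generate_cohort(cohort.default_spec(n_patients=160, seed=21))
    return df[["wbc", "bmi", "approach", "age", "crp", "ppc"]]


class TestDecodeSolution:
    def test_model_id_bins(self, space):
        m = 4
        for raw0, k in [(0.0, 1), (0.24, 1), (0.26, 2), (0.5, 3), (0.99, 4),
                        (1.0, 4)]:
            raw = np.concatenate([[raw0], np.full(m, 0.9),
                                  np.full(space.n_genes, 0.5)])
            assert automl.decode_solution(raw, space, m).k == k

    def test_empty_mask_repaired_to_max_gene(self, space):
        raw = np.concatenate([[0.1], [0.4, 0.45, 0.2, 0.1],
                              np.full(space.n_genes, 0.5)])
        sol = automl.decode_solution(raw, space, 4)
        assert sol.delta.sum() == 1
        assert sol.delta[1]  # the largest feature gene

    def test_log_scale_midpoint_learning_rate(self, space):
        # LightGBM learning-rate gene 0.5 on log [1e-5, 1e-1] -> 1e-3
        raw = np.concatenate([[0.99], np.full(3, 0.9),
                              np.full(space.n_genes, 0.5)])
        sol = automl.decode_solution(raw, space, 3)
        assert sol.k == 4
        assert sol.hyperparams["learning_rate"] == pytest.approx(1e-3)

    def test_integer_parameter_rounded_and_bounded(self, space):
        for g in np.linspace(0, 1, 11):
            raw = np.concatenate([[0.8], [0.9, 0.9],
                                  np.full(space.n_genes, g)])
            sol = automl.decode_solution(raw, space, 2)
            assert sol.hyperparams["max_depth"] == round(3 + g * 9)
            assert 3 <= sol.hyperparams["max_depth"] <= 12

    def test_decoded_hyperparams_within_declared_ranges(self, space, rng):
        for _ in range(50):
            raw = rng.random(1 + 5 + space.n_genes)
            sol = automl.decode_solution(raw, space, 5)
            for p in space.params[sol.k]:
                assert p.low <= sol.hyperparams[p.name] <= p.high

    def test_wrong_length_rejected(self, space):
        with pytest.raises(ValueError):
            automl.decode_solution(np.zeros(3), space, 5)


class TestCvFitness:
    def test_decomposition_reconstructs_fitness(self, tiny_train, space):
        weights = automl.FitnessWeights()
        raw = np.concatenate([[0.1], np.full(5, 0.9), np.full(space.n_genes, 0.5)])
        sol = automl.decode_solution(raw, space, 5)
        comp = automl.fitness_components(
            sol, tiny_train, weights, t=0.5, folds=4, n_estimators=15
        )
        rebuilt = (comp["w1"] * comp["cv_accuracy"]
                   + comp["w2"] * comp["sparsity"]
                   + comp["w3"] * comp["efficiency"])
        assert comp["fitness"] == pytest.approx(rebuilt, abs=1e-12)

    def test_sparsity_term_arithmetic(self, tiny_train, space):
        # identical model, 2 of 5 vs 5 of 5 features: sparsity differs by
        # exactly w2 * 3/5 in the weighted fitness
        weights = automl.FitnessWeights(w2_start=0.2, w2_end=0.2)
        full = automl.decode_solution(
            np.concatenate([[0.1], np.full(5, 0.9), np.full(space.n_genes, 0.5)]),
            space, 5,
        )
        sparse = automl.decode_solution(
            np.concatenate([[0.1], [0.9, 0.9, 0.1, 0.1, 0.1],
                            np.full(space.n_genes, 0.5)]),
            space, 5,
        )
        c_full = automl.fitness_components(full, tiny_train, weights, 0.0, folds=4)
        c_sparse = automl.fitness_components(sparse, tiny_train, weights, 0.0,
                                             folds=4)
        assert c_sparse["sparsity"] - c_full["sparsity"] == pytest.approx(3 / 5)

    def test_perfectly_separable_data_hits_accuracy_ceiling(self, space):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        df = pd.DataFrame({"x": x, "noise": np.tile([0.1, 0.9], 20),
                           "ppc": x.astype(int)})
        weights = automl.FitnessWeights(w2_start=0.0, w2_end=0.0, w3=0.0)
        sol = automl.decode_solution(
            np.concatenate([[0.1], [0.9, 0.1], np.full(space.n_genes, 0.5)]),
            space, 2,
        )
        fit = automl.cv_fitness(sol, df, weights, t=0.0, folds=4)
        assert fit == pytest.approx(weights.w1(0.0) * 1.0)

    def test_deterministic_across_calls(self, tiny_train, space):
        weights = automl.FitnessWeights()
        sol = automl.decode_solution(
            np.concatenate([[0.9], np.full(5, 0.9), np.full(space.n_genes, 0.6)]),
            space, 5,
        )
        vals = {
            automl.cv_fitness(sol, tiny_train, weights, 0.3, seed=4, folds=4,
                              n_estimators=15)
            for _ in range(3)
        }
        assert len(vals) == 1


class TestSearch:
    @pytest.fixture(scope="class")
    def result(self, tiny_train):
        return automl.search(
            tiny_train, seed=5, folds=4,
            space=automl.default_space(n_estimators=15),
            population_size=6, max_iterations=3,
            confirm_top=3, confirm_cv_repeats=2,
        )

    def test_trace_monotone_nondecreasing(self, result):
        assert (np.diff(result.trace) >= -1e-12).all()

    def test_selected_features_nonempty_and_valid(self, result, tiny_train):
        assert len(result.selected_features) >= 1
        assert set(result.selected_features) <= set(tiny_train.columns) - {"ppc"}

    def test_model_probabilities_valid(self, result, tiny_train):
        p = result.model.predict_proba(tiny_train)
        assert ((p >= 0) & (p <= 1)).all()

    def test_deterministic_under_seed(self, tiny_train, result):
        again = automl.search(
            tiny_train, seed=5, folds=4,
            space=automl.default_space(n_estimators=15),
            population_size=6, max_iterations=3,
            confirm_top=3, confirm_cv_repeats=2,
        )
        assert again.best_solution.k == result.best_solution.k
        assert np.array_equal(again.best_solution.delta,
                              result.best_solution.delta)
        assert np.array_equal(again.trace, result.trace)

    def test_too_few_rows_per_class_rejected(self):
        df = pd.DataFrame({"x": np.arange(8.0), "ppc": [1, 0] * 4})
        with pytest.raises(ValueError):
            automl.search(df, folds=10)


class TestBaselines:
    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    def test_probability_contract(self, model_id, tiny_train):
        model = automl.fit_baseline(model_id, tiny_train, seed=0)
        p = model.predict_proba(tiny_train)
        assert p.shape == (len(tiny_train),)
        assert ((p >= 0) & (p <= 1)).all()

    def test_lr_separates_separable_toy_data(self):
        x = np.concatenate([np.full(15, -2.0), np.full(15, 2.0)])
        df = pd.DataFrame({"x": x, "ppc": (x > 0).astype(int)})
        model = automl.fit_baseline(1, df, seed=0)
        pred = (model.predict_proba(df) >= 0.5).astype(int)
        assert (pred == df["ppc"].to_numpy()).all()

    def test_missing_feature_column_rejected(self, tiny_train):
        model = automl.fit_baseline(1, tiny_train, seed=0)
        with pytest.raises(ValueError):
            model.predict_proba(tiny_train[["wbc"]])
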