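"""Ensemble model core: splits, base learners, AUC, importance, weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coastsdm.ensemble import (
    ALGORITHMS,
    CVConfig,
    EnsembleSDM,
    ModelRun,
    NoSkillfulModelsError,
    auc,
    build_importance_table,
    ensemble_predict,
    fit_single,
    run_cross_validation,
    split_calibration,
    variable_importance,
)

from oracles import auc_enumeration


def toy_table(rng, n=100, informative=True):
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    logit = 2.0 * x if informative else np.zeros(n)
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    # ensure both classes
    y[0], y[1] = 0, 1
    return pd.DataFrame({"x": x, "z": z, "response": y})


class TestSplit:
    def test_balanced_75_25(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.normal(size=100), "response": [0, 1] * 50})
        calib, test = split_calibration(table, CVConfig(seed=1), run_index=1)
        assert len(calib) == 75 and len(test) == 25
        assert abs(calib.response.sum() - 37.5) <= 1
        assert abs(test.response.sum() - 12.5) <= 1

    def test_deterministic_per_run_index(self):
        rng = np.random.default_rng(1)
        table = toy_table(rng)
        a1, b1 = split_calibration(table, CVConfig(seed=3), 2)
        a2, b2 = split_calibration(table, CVConfig(seed=3), 2)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_runs_produce_distinct_reproducible_splits(self):
        rng = np.random.default_rng(2)
        table = toy_table(rng)
        config = CVConfig(seed=5, n_runs=10)
        seen = set()
        for run in range(1, 11):
            calib, _ = split_calibration(table, config, run)
            seen.add(tuple(calib.index))
        assert len(seen) == 10

    def test_too_small_table_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2], "response": [0, 1]})
        with pytest.raises(ValueError):
            split_calibration(table, CVConfig(), 1)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_enumerated_example(self):
        assert auc([0.9, 0.8, 0.3, 0.4], [1, 1, 1, 0]) == pytest.approx(2 / 3)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.4], [1, 1])

    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 1)),
            min_size=2,
            max_size=12,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_enumeration_oracle(self, pairs):
        scores = np.array([p[0] for p in pairs], dtype=float) / 4.0
        labels = np.array([p[1] for p in pairs])
        if labels.min() == labels.max():
            return
        assert auc(scores, labels) == pytest.approx(
            auc_enumeration(scores, labels), abs=1e-12
        )


class TestFitSingle:
    def test_perfect_separator_cta(self):
        table = pd.DataFrame(
            {"x": np.r_[np.zeros(20), np.ones(20)], "response": [0] * 20 + [1] * 20}
        )
        model = fit_single("CTA", table, ["x"])
        assert auc(model.predict_prob(table), table.response) == 1.0

    def test_null_response_gives_chance_level_test_auc(self):
        """Response independent of predictors -> test AUC centred near 0.5."""
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table = toy_table(rng, n=80, informative=False)
            config = CVConfig(seed=seed, algorithms=("CTA",), n_runs=1)
            calib, test = split_calibration(table, config, 1)
            model = fit_single("CTA", calib, ["x", "z"], random_state=seed)
            aucs.append(auc(model.predict_prob(test), test.response))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_gam_recovers_unimodal_depth_effect(self):
        """GAM fitted to a smooth depth preference shows an interior maximum."""
        rng = np.random.default_rng(4)
        depth = rng.uniform(0, 40, 400)
        logit = 1.5 - ((depth - 12.0) / 6.0) ** 2
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-logit))).astype(int)
        table = pd.DataFrame({"depth": depth, "response": y})
        model = fit_single("GAM", table, ["depth"])
        grid = pd.DataFrame({"depth": np.linspace(0, 40, 200)})
        pred = model.predict_prob(grid)
        peak = grid.depth[np.argmax(pred)]
        assert 6.0 < peak < 20.0
        assert pred.max() > pred[0] and pred.max() > pred[len(pred) - 1]

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_every_algorithm_emits_probabilities(self, algorithm):
        rng = np.random.default_rng(6)
        table = toy_table(rng, n=60)
        table["habitat"] = rng.choice(["sand", "reef"], size=60)
        model = fit_single(algorithm, table, ["x", "z", "habitat"])
        p = model.predict_prob(table)
        assert p.shape == (60,)
        assert np.all((p >= 0) & (p <= 1))


class TestImportance:
    def test_unused_column_has_zero_importance(self):
        rng = np.random.default_rng(1)
        table = toy_table(rng)
        model = fit_single("GAM", table, ["x", "z"])

        class IgnoreZ:
            predictors = ["x", "z"]

            def predict_prob(self, rows):
                return 1 / (1 + np.exp(-rows["x"].to_numpy()))

        imp = variable_importance(IgnoreZ(), table, n_perm=5, seed=0)
        assert imp["z"] == 0.0
        assert imp["x"] > 0.5

    def test_identity_predictor_near_one(self):
        rng = np.random.default_rng(2)
        rows = pd.DataFrame({"v": rng.normal(size=200)})

        class Identity:
            predictors = ["v"]

            def predict_prob(self, r):
                return 1 / (1 + np.exp(-r["v"].to_numpy()))

        imp = variable_importance(Identity(), rows, n_perm=10, seed=1)
        assert imp["v"] > 0.5

    def test_duplicated_columns_share_importance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=300)
        rows = pd.DataFrame({"a": v, "b": v.copy()})

        class Additive:
            predictors = ["a", "b"]

            def predict_prob(self, r):
                s = r["a"].to_numpy() + r["b"].to_numpy()
                return 1 / (1 + np.exp(-s))

        imp = variable_importance(Additive(), rows, n_perm=20, seed=2)
        assert imp["a"] == pytest.approx(imp["b"], abs=0.1)

    def test_constant_predictions_zero_importance(self):
        rows = pd.DataFrame({"a": [1.0, 2, 3, 4]})

        class Flat:
            predictors = ["a"]

            def predict_prob(self, r):
                return np.full(len(r), 0.4)

        imp = variable_importance(Flat(), rows)
        assert imp == {"a": 0.0}

    def test_clipped_to_unit_interval(self):
        rng = np.random.default_rng(4)
        rows = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})

        class Noisy:
            predictors = ["a", "b"]

            def predict_prob(self, r):
                return (np.sign(r["a"].to_numpy()) + 1) / 2

        imp = variable_importance(Noisy(), rows, n_perm=10, seed=3)
        assert all(0.0 <= v <= 1.0 for v in imp.values())


class TestCrossValidationAndEnsemble:
    def test_runs_count_full_panel(self):
        rng = np.random.default_rng(5)
        table = toy_table(rng, n=120)
        config = CVConfig(seed=2, n_runs=2, n_importance_perm=2)
        runs = run_cross_validation(table, config)
        assert len(runs) == 12  # 6 algorithms x 2 runs

    def test_single_run_single_algorithm(self):
        rng = np.random.default_rng(6)
        table = toy_table(rng, n=60)
        runs = run_cross_validation(
            table, CVConfig(seed=1, n_runs=1, algorithms=("GAM",), n_importance_perm=2)
        )
        assert len(runs) == 1
        assert 0.0 <= runs[0].auc_test <= 1.0

    def test_deterministic_auc_vector(self):
        rng = np.random.default_rng(7)
        table = toy_table(rng, n=80)
        config = CVConfig(seed=9, n_runs=2, algorithms=("CTA", "RF"), n_importance_perm=2)
        a = [r.auc_test for r in run_cross_validation(table, config)]
        b = [r.auc_test for r in run_cross_validation(table, config)]
        assert a == b

    def test_importance_table_arithmetic(self):
        def mk(alg, run, imp):
            return ModelRun(alg, run, 0, 0.8, imp, model=None)

        runs = [
            mk("GAM", 1, {"a": 0.2, "b": 0.6}),
            mk("GAM", 2, {"a": 0.4, "b": 0.0}),
            mk("RF", 1, {"a": 0.9, "b": 0.1}),
        ]
        table = build_importance_table(runs)
        assert table.loc["GAM", "a"] == pytest.approx(0.3)
        assert table.loc["Mean of means", "a"] == pytest.approx((0.3 + 0.9) / 2)

    def test_single_run_table_equals_its_importance(self):
        runs = [ModelRun("RF", 1, 0, 0.9, {"a": 0.5, "b": 0.25}, model=None)]
        table = build_importance_table(runs)
        assert table.loc["RF", "a"] == 0.5
        assert table.loc["Mean of means", "b"] == 0.25

    def test_ensemble_weight_formula(self):
        class Const:
            def __init__(self, value):
                self.value = value

            def predict_prob(self, rows):
                return np.full(len(rows), self.value)

        runs = [
            ModelRun("A", 1, 0, 0.6, {}, Const(0.2)),
            ModelRun("B", 1, 0, 0.8, {}, Const(0.9)),
        ]
        features = pd.DataFrame({"x": [0.0, 1.0]})
        surface = ensemble_predict(runs, features)
        assert surface.probability[0] == pytest.approx((0.6 * 0.2 + 0.8 * 0.9) / 1.4)
        assert sum(surface.weights.values()) == pytest.approx(1.0)

    def test_single_included_run_identity(self):
        class Ramp:
            def predict_prob(self, rows):
                return rows["x"].to_numpy()

        runs = [ModelRun("A", 1, 0, 0.7, {}, Ramp())]
        features = pd.DataFrame({"x": [0.1, 0.5, 0.9]})
        surface = ensemble_predict(runs, features)
        assert np.allclose(surface.probability, [0.1, 0.5, 0.9])
        assert surface.weights[("A", 1)] == 1.0

    def test_chance_level_run_excluded(self):
        class Const:
            def predict_prob(self, rows):
                return np.full(len(rows), 0.5)

        runs = [
            ModelRun("A", 1, 0, 0.5, {}, Const()),  # exactly 0.5 -> excluded
            ModelRun("B", 1, 0, 0.7, {}, Const()),
        ]
        surface = ensemble_predict(runs, pd.DataFrame({"x": [0.0]}))
        assert ("A", 1) not in surface.weights

    def test_no_skillful_models_raises(self):
        class Const:
            def predict_prob(self, rows):
                return np.full(len(rows), 0.5)

        runs = [ModelRun("A", 1, 0, 0.45, {}, Const())]
        with pytest.raises(NoSkillfulModelsError):
            ensemble_predict(runs, pd.DataFrame({"x": [0.0]}))

    def test_ensemble_probability_is_convex_combination(self):
        rng = np.random.default_rng(8)
        table = toy_table(rng, n=100)
        results = EnsembleSDM.from_feature_table(table).fit(
            n_runs=2, seed=3, n_importance_perm=2
        )
        features = table[["x", "z"]].assign(cell_id=np.arange(len(table)))
        surface = results.predict(features)
        included = [
            r for r in results.runs if (r.algorithm, r.run_index) in surface.weights
        ]
        preds = np.stack([r.model.predict_prob(features) for r in included])
        assert np.all(surface.probability >= preds.min(axis=0) - 1e-12)
        assert np.all(surface.probability <= preds.max(axis=0) + 1e-12)

    def test_summary_reports_core_quantities(self):
        rng = np.random.default_rng(9)
        table = toy_table(rng, n=90)
        results = EnsembleSDM.from_feature_table(table, algorithms=("GAM", "CTA")).fit(
            n_runs=2, seed=4, n_importance_perm=2
        )
        text = results.summary()
        assert "ensemble AUC" in text and "GAM" in text

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CVConfig(calib_fraction=1.2)
        with pytest.raises(ValueError):
            CVConfig(algorithms=("SVM",))
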