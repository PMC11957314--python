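"""Forest-modelling contracts: splits, fits, metrics, importances, leakage."""
import numpy as np
import pandas as pd
import pytest

from myoscreen import (
    ModelSpec,
    SmognConfig,
    evaluate,
    fit_rf,
    global_model,
    importance_matrix,
    per_compound_models,
    split_train_test,
)
from myoscreen.models import GLOBAL_SCOPE, ModelReport
from myoscreen.smogn import make_augmenter


class TestSplit:
    def test_96_rows_gives_76_20(self):
        X, y = np.zeros((96, 2)), np.zeros(96)
        train, test = split_train_test(X, y, ModelSpec(seed=1))
        assert (len(train), len(test)) == (76, 20)
        assert set(train).isdisjoint(test)
        assert sorted(np.concatenate([train, test])) == list(range(96))

    def test_five_rows_gives_4_1(self):
        train, test = split_train_test(np.zeros((5, 1)), np.zeros(5), ModelSpec(seed=1))
        assert (len(train), len(test)) == (4, 1)

    def test_same_seed_identical_split(self):
        X, y = np.zeros((50, 2)), np.zeros(50)
        a = split_train_test(X, y, ModelSpec(seed=9))
        b = split_train_test(X, y, ModelSpec(seed=9))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            split_train_test(np.zeros((4, 1)), np.zeros(4), ModelSpec())


class TestFitRF:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        model = fit_rf(X, np.full(30, 5.5), ModelSpec(seed=1))
        np.testing.assert_allclose(model.predict(X), 5.5)

    def test_noiseless_linear_signal_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        y = 3.0 * X[:, 0]
        spec = ModelSpec(seed=2)
        train, test = split_train_test(X, y, spec)
        model = fit_rf(X[train], y[train], spec)
        r2, _ = evaluate(model, X[test], y[test])
        assert r2 >= 0.95

    def test_refit_is_bit_identical(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        a = fit_rf(X, y, ModelSpec(seed=3)).predict(X)
        b = fit_rf(X, y, ModelSpec(seed=3)).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fit_rf(np.zeros((1, 2)), np.zeros(1), ModelSpec())


class TestEvaluate:
    def _mean_model(self, value):
        class M:
            def predict(self, X):
                return np.full(len(X), value)

        return M()

    def test_perfect_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        y = X[:, 0]

        class Ident:
            def predict(self, X):
                return X[:, 0]

        r2, mse = evaluate(Ident(), X, y)
        assert (r2, mse) == (1.0, 0.0)

    def test_predict_the_mean_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = evaluate(self._mean_model(y.mean()), np.zeros((4, 1)), y)
        assert r2 == pytest.approx(0.0)

    def test_matches_hand_computed_ss_ratio(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        pred = y + rng.normal(0, 0.5, size=30)

        class Fixed:
            def predict(self, X):
                return pred

        r2, mse = evaluate(Fixed(), np.zeros((30, 1)), y)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        assert r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
        assert mse == pytest.approx(ss_res / 30, rel=1e-12)

    def test_zero_variance_target_flagged(self):
        r2, mse = evaluate(self._mean_model(2.0), np.zeros((3, 1)), np.full(3, 1.0))
        assert np.isnan(r2)
        assert mse == pytest.approx(1.0)


@pytest.fixture(scope="module")
def reports(small_run, model_spec):
    return per_compound_models(
        small_run.filtered,
        small_run.targets,
        model_spec,
        target_names=("viability_pct", "target_cell_count"),
    )


class TestPerCompound:

    def test_one_report_per_compound_per_target(self, small_run, reports):
        assert len(reports) == small_run.cfg.n_compounds * 2
        assert all(r.scope != "VEHICLE" for r in reports)

    def test_importances_sum_to_one(self, reports):
        for r in reports:
            assert r.importances.sum() == pytest.approx(1.0, abs=1e-9)
            assert (r.importances >= 0).all()

    def test_no_effect_compound_flagged_low_variance(self, small_run, reports):
        tf = small_run.truth.compounds_frame()
        inert = set(tf.loc[~tf["toxic"], "compound"])
        flags = {
            r.scope: r.low_variance
            for r in reports
            if r.target == "viability_pct"
        }
        assert all(flags[c] for c in inert)

    def test_strong_toxicant_predicts_well(self, small_run, reports):
        tf = small_run.truth.compounds_frame()
        strong = tf.loc[
            (tf["emax_atp"] >= 0.9), "compound"
        ]
        r2 = {
            r.scope: r.r2_test for r in reports if r.target == "viability_pct"
        }
        assert max(r2[c] for c in strong) >= 0.8

    def test_train_test_disjoint_in_every_report(self, reports):
        for r in reports:
            assert set(r.train_ids).isdisjoint(r.test_ids)


class TestGlobalModel:
    def test_leakage_guard_same_test_rows_with_and_without_smogn(
        self, small_run, model_spec
    ):
        plain = global_model(
            small_run.filtered, small_run.targets, model_spec, "viability_pct"
        )
        aug = global_model(
            small_run.filtered,
            small_run.targets,
            model_spec,
            "viability_pct",
            augmenter=make_augmenter(SmognConfig(seed=5)),
        )
        assert plain.test_ids == aug.test_ids
        assert aug.augmented and not plain.augmented
        assert plain.scope == GLOBAL_SCOPE

    def test_needs_two_compounds(self, small_run, model_spec):
        pm = small_run.filtered
        one = pm.data[pm.data["compound"].isin(["C002", "VEHICLE"])]
        from myoscreen.profiling import ProfileMatrix

        sub = ProfileMatrix(
            data=one.reset_index(drop=True),
            features=pm.features,
            normalization=pm.normalization,
        )
        with pytest.raises(ValueError, match="2 compounds"):
            global_model(sub, small_run.targets, model_spec, "viability_pct")


def _report(scope, importances):
    s = pd.Series(importances)
    return ModelReport(
        scope=scope,
        target="viability_pct",
        r2_train=1.0,
        r2_test=1.0,
        mse_train=0.0,
        mse_test=0.0,
        n_train=10,
        n_test=3,
        importances=s / s.sum(),
    )


class TestImportanceMatrix:
    def test_median_rank_ordering_matches_hand_computation(self):
        reports = [
            _report("M1", {"a": 0.5, "b": 0.3, "c": 0.1, "d": 0.06, "e": 0.04}),
            _report("M2", {"a": 0.1, "b": 0.5, "c": 0.3, "d": 0.06, "e": 0.04}),
            _report("M3", {"a": 0.5, "b": 0.1, "c": 0.3, "d": 0.06, "e": 0.04}),
        ]
        # per-model descending ranks: a:[1,3,1] b:[2,1,3] c:[3,2,2] d:[4,4,4]
        # e:[5,5,5]; median ranks a:1 b:2 c:2 d:4 e:5 (b before c: column order)
        matrix, _, _ = importance_matrix(reports, k=4)
        assert list(matrix.columns) == ["a", "b", "c", "d"]
        assert list(matrix.index) == ["M1", "M2", "M3"]

    def test_identical_models_merge_at_height_zero(self):
        imp = {"a": 0.6, "b": 0.3, "c": 0.1}
        reports = [
            _report("M1", imp),
            _report("M2", imp),
            _report("M3", {"a": 0.1, "b": 0.2, "c": 0.7}),
        ]
        _, row_res, _ = importance_matrix(reports, k=3)
        assert row_res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_features_than_k_keeps_all(self):
        reports = [
            _report("M1", {"a": 0.7, "b": 0.3}),
            _report("M2", {"a": 0.2, "b": 0.8}),
        ]
        matrix, _, _ = importance_matrix(reports, k=30)
        assert set(matrix.columns) == {"a", "b"}

    def test_duplicate_scopes_rejected(self):
        reports = [
            _report("M1", {"a": 0.7, "b": 0.3}),
            _report("M1", {"a": 0.2, "b": 0.8}),
        ]
        with pytest.raises(ValueError, match="unique"):
            importance_matrix(reports)
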