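import numpy as np
import pandas as pd
import pytest

from metarisk import (
    CVPlan, RLSConfig, CohortTable, stratified_folds, nested_cv,
    panel_union, external_validation, generate_cohort,
    generate_validation_cohort, SyntheticConfig, standardise,
    impute_minimum, fit_rls, auc, delong_test, benchmark_config,
)
from metarisk.crossval import NestedCVResult, MarkerPanel, _select_lambda


def _feature_cohort(X, y, names=None):
    ids = pd.Index([f"s{i}" for i in range(len(y))], name="sample_id")
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return CohortTable(
        features=pd.DataFrame(X, index=ids, columns=names),
        covariates=pd.DataFrame(index=ids),
        outcome=pd.Series(np.asarray(y, int), index=ids))


class TestStratifiedFolds:
    def test_balanced_counts(self):
        y = np.r_[np.ones(146, int), np.zeros(397, int)]
        folds = stratified_folds(y, 10, seed=0)
        for cls, (lo, hi) in ((1, (14, 15)), (0, (39, 40))):
            counts = np.bincount(folds[y == cls], minlength=10)
            assert counts.min() >= lo and counts.max() <= hi

    def test_partition_exhaustive_disjoint(self, rng):
        y = (rng.uniform(size=83) < 0.4).astype(int)
        folds = stratified_folds(y, 5, seed=3)
        assert folds.size == 83
        assert set(folds) == set(range(5))

    def test_loo_partition(self):
        y = np.r_[np.ones(4, int), np.zeros(4, int)]
        folds = stratified_folds(y, 8, seed=1)
        assert sorted(folds) == list(range(8))

    def test_minority_bound(self):
        y = np.r_[np.ones(3, int), np.zeros(20, int)]
        with pytest.raises(ValueError, match="minority"):
            stratified_folds(y, 5, seed=0)

    def test_pure_function_of_seed(self):
        y = np.r_[np.ones(30, int), np.zeros(50, int)]
        np.testing.assert_array_equal(stratified_folds(y, 4, seed=9),
                                      stratified_folds(y, 4, seed=9))


class TestNestedCV:
    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 10))
        y = (rng.uniform(size=80) < 0.4).astype(int)
        t = _feature_cohort(X, y)
        plan = CVPlan(outer_folds=5, inner_folds=3, repetitions=1, seed=7)
        cfg = RLSConfig(lambda_grid=(0.1, 1.0, 10.0))
        a = nested_cv(t, t.feature_names, cfg, plan)
        b = nested_cv(t, t.feature_names, cfg, plan)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.fold_lambdas, b.fold_lambdas)

    def test_every_sample_scored_once(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 5))
        y = (rng.uniform(size=60) < 0.5).astype(int)
        t = _feature_cohort(X, y)
        plan = CVPlan(outer_folds=4, inner_folds=3, repetitions=3, seed=0)
        res = nested_cv(t, t.feature_names, RLSConfig(lambda_grid=(1.0,)), plan)
        assert res.scores.shape == (3, 60)
        assert np.isfinite(res.scores).all()
        # fold assignment covers all samples each repetition
        for r in range(3):
            assert set(res.fold_assignments[r]) == set(range(4))

    def test_null_features_auc_near_half(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((150, 20))
        y = np.r_[np.ones(50, int), np.zeros(100, int)]
        t = _feature_cohort(X, y)
        plan = CVPlan(outer_folds=5, inner_folds=3, repetitions=5, seed=0)
        res = nested_cv(t, t.feature_names,
                        RLSConfig(lambda_grid=(0.25, 4.0, 64.0)), plan)
        assert 0.4 <= res.aucs.mean() <= 0.6

    def test_all_tied_inner_aucs_pick_smallest_lambda(self):
        # single informative feature: any penalty yields the same ranking
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60)
        y = (x + 0.2 * rng.standard_normal(60) > 0).astype(int)
        grid = (0.5, 2.0, 8.0)
        lam = _select_lambda(x[:, None], y, np.array(grid), 3,
                             np.random.default_rng(0), True)
        assert lam == 0.5

    def test_leakage_canary(self):
        # a feature equal to the outcome on one outer-test fold only (zero
        # elsewhere) must not lift that repetition's AUC: the training fold
        # sees a constant column
        rng = np.random.default_rng(8)
        n = 120
        y = np.r_[np.ones(40, int), np.zeros(80, int)]
        X = rng.standard_normal((n, 6))
        plan = CVPlan(outer_folds=4, inner_folds=3, repetitions=1, seed=13)
        fold_rng = np.random.default_rng(plan.seed + 0)
        folds = stratified_folds(y, plan.outer_folds, fold_rng)
        canary = np.where(folds == 0, np.where(y > 0, 1.0, -1.0), 0.0)
        X = np.column_stack([X, canary])
        t = _feature_cohort(X, y)
        res = nested_cv(t, t.feature_names, RLSConfig(lambda_grid=(1.0, 8.0)),
                        plan, fold_standardise=True)
        assert 0.3 <= res.aucs[0] <= 0.7

    def test_selection_recorded_per_repetition(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((100, 15))
        lp = 1.5 * X[:, 3] - 1.2 * X[:, 9]
        y = (rng.uniform(size=100) < 1 / (1 + np.exp(-lp))).astype(int)
        t = _feature_cohort(X, y)
        plan = CVPlan(outer_folds=5, inner_folds=3, repetitions=3, seed=1)
        res = nested_cv(t, t.feature_names, RLSConfig(lambda_grid=(1.0, 4.0)),
                        plan, select_k=2)
        assert len(res.selections) == 3
        assert all(len(sel) == 2 for sel in res.selections)
        top = {f for sel in res.selections for f in sel}
        assert "f3" in top and "f9" in top

    def test_outer_union_scope(self):
        rng = np.random.default_rng(22)
        X = rng.standard_normal((80, 8))
        y = (X[:, 0] > 0).astype(int)
        t = _feature_cohort(X, y)
        plan = CVPlan(outer_folds=4, inner_folds=3, repetitions=1, seed=2)
        res = nested_cv(t, t.feature_names, RLSConfig(lambda_grid=(1.0,)),
                        plan, select_k=1, selection_scope="outer-union")
        assert res.selections[0][0] == "f0"

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((40, 4))
        y = (rng.uniform(size=40) < 0.5).astype(int)
        t = _feature_cohort(X, y)
        plan = CVPlan(outer_folds=3, inner_folds=2, repetitions=2, seed=0)
        res = nested_cv(t, t.feature_names, RLSConfig(lambda_grid=(1.0, 2.0)),
                        plan, select_k=1)
        path = tmp_path / "res.json"
        res.save(path)
        back = NestedCVResult.load(path)
        np.testing.assert_allclose(back.scores, res.scores)
        assert back.selections == res.selections


class TestPanelUnion:
    def _result_with(self, selections):
        n = 4
        return NestedCVResult(
            model_spec="m", sample_ids=list("abcd"),
            outcome=np.array([0, 1, 0, 1]), feature_names=["x"],
            scores=np.zeros((len(selections), n)),
            fold_assignments=np.zeros((len(selections), n), int),
            fold_lambdas=np.ones((len(selections), 1)),
            aucs=np.full(len(selections), 0.5), selections=selections,
            select_k=2)

    def test_identical_selections(self):
        panel = panel_union(self._result_with([["a", "b"]] * 4))
        assert panel.feature_names == ["a", "b"]
        assert all(f == 1.0 for _, f in panel.union)

    def test_set_arithmetic(self):
        panel = panel_union(self._result_with([["A", "B"], ["B", "C"]]))
        assert dict(panel.union) == {"A": 0.5, "B": 1.0, "C": 0.5}
        assert panel.union[0][0] == "B"  # sorted by frequency first

    def test_requires_selection(self):
        res = self._result_with([["a"]])
        res.selections = None
        with pytest.raises(ValueError):
            panel_union(res)

    def test_roundtrip(self, tmp_path):
        panel = panel_union(self._result_with([["A", "B"], ["B", "C"]]))
        panel.save(tmp_path / "p.json")
        back = MarkerPanel.load(tmp_path / "p.json")
        assert back.union == panel.union


class TestExternalValidation:
    def _cohorts(self):
        config = SyntheticConfig(
            n_samples=220, n_progressors=60, n_targeted=3, n_untargeted=7,
            planted_effects=(("a", 0.9), ("b", -0.7)),
            covariate_model={}, seed=17)
        train = generate_cohort(config)
        train, _ = standardise(impute_minimum(train))
        valid = generate_validation_cohort(config, ["a", "b"])
        valid = impute_minimum(valid)
        return train, valid

    def test_single_repetition_equals_single_fit(self):
        train, valid = self._cohorts()
        plan = CVPlan(outer_folds=3, inner_folds=3, repetitions=1, seed=4)
        cfg = RLSConfig(lambda_grid=(0.5, 2.0))
        out = external_validation(train, valid, ["a", "b"], cfg, plan)
        model = out.averaged_model
        scores = out.scores
        # refit once with the recorded penalty and the same scaling
        from metarisk.cohort import design_matrix
        X_tr, _ = design_matrix(train, ["a", "b"], standardise=False)
        X_va, _ = design_matrix(valid, ["a", "b"], standardise=False)
        mu, sd = X_tr.mean(0), X_tr.std(0, ddof=1)
        single = fit_rls((X_tr - mu) / sd, train.outcome.to_numpy(),
                         RLSConfig(lam=out.rep_lambdas[0]))
        np.testing.assert_allclose(model.weights, single.weights, atol=1e-12)
        np.testing.assert_allclose(
            scores, (X_va - mu) / sd @ single.weights + single.intercept_value)

    def test_averaging_identical_models(self):
        train, valid = self._cohorts()
        cfg = RLSConfig(lambda_grid=(1.0,))  # single grid point: every
        plan = CVPlan(outer_folds=3, inner_folds=3, repetitions=4, seed=0)
        out = external_validation(train, valid, ["a", "b"], cfg, plan)
        assert np.unique(out.rep_lambdas).size == 1
        single = external_validation(train, valid, ["a", "b"], cfg,
                                     CVPlan(outer_folds=3, inner_folds=3,
                                            repetitions=1, seed=0))
        np.testing.assert_allclose(out.averaged_model.weights,
                                   single.averaged_model.weights)

    def test_missing_feature_listed(self):
        train, valid = self._cohorts()
        plan = CVPlan(outer_folds=3, inner_folds=3, repetitions=1, seed=0)
        with pytest.raises(ValueError, match="f0"):
            external_validation(train, valid, ["a", "f0"],
                                RLSConfig(lambda_grid=(1.0,)), plan)

    def test_transfer_improves_over_clinical(self):
        # external replication: markers + clinical beat clinical alone
        from dataclasses import replace
        config = replace(benchmark_config(seed=31), n_samples=400,
                         n_progressors=110)
        train, _ = standardise(impute_minimum(generate_cohort(config)))
        vconfig = replace(config, n_samples=600, n_progressors=140)
        valid = impute_minimum(generate_validation_cohort(
            vconfig, ["glucose", "mannose", "alpha_HB", "alpha_tocopherol"]))
        clinical = ["age", "bmi", "fasting_insulin"]
        plan = CVPlan(outer_folds=5, inner_folds=3, repetitions=3, seed=0)
        cfg = RLSConfig(lambda_grid=(0.5, 4.0, 32.0, 256.0))
        combined = external_validation(
            train, valid, ["glucose", "mannose", "alpha_HB",
                           "alpha_tocopherol"] + clinical, cfg, plan)
        clin = external_validation(train, valid, clinical, cfg, plan)
        y = valid.outcome.to_numpy()
        auc_combined = auc(combined.scores, y)
        auc_clin = auc(clin.scores, y)
        assert auc_combined > auc_clin
        assert delong_test(combined.scores, clin.scores, y).p_value < 0.05
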