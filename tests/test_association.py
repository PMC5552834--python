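import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metarisk import (
    CohortTable, logistic_fit, feature_association, qvalues,
    association_screen, baseline_characteristics, generate_cohort,
    SyntheticConfig, standardise, impute_minimum,
)
from metarisk.association import (
    welch_from_summary, screen_frame, ConvergenceError,
)


def _binary_predictor_counts(a, b, c, d):
    """Outcome/exposure from a 2x2 table (rows = exposure, cols = outcome)."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return x, y


class TestLogisticFit:
    def test_cross_product_identity(self):
        # family-history-style counts: OR = (27*99)/(3*190)
        x, y = _binary_predictor_counts(27, 190, 3, 99)
        fit = logistic_fit(x[:, None], y)
        assert np.exp(fit.coef[1]) == pytest.approx(
            (27 * 99) / (3 * 190), abs=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        X = rng.standard_normal((300, 3))
        y = (rng.uniform(size=300) <
             1 / (1 + np.exp(-(0.3 + X @ [0.5, -0.8, 0.2])))).astype(float)
        fit = logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-5)

    def test_null_or_near_one(self, rng):
        x = rng.standard_normal(10_000)
        y = (rng.uniform(size=10_000) < 0.3).astype(float)
        fit = logistic_fit(x[:, None], y)
        assert np.exp(fit.coef[1]) == pytest.approx(1.0, abs=0.08)

    def test_separation_flagged(self):
        x = np.r_[np.ones(20), -np.ones(20)]
        y = np.r_[np.ones(20), np.zeros(20)]
        fit = logistic_fit(x[:, None], y)
        assert fit.separation

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(np.ones((10, 1)), np.r_[np.ones(5), np.zeros(5)])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            logistic_fit(np.arange(6.0)[:, None], np.ones(6))


class TestFeatureAssociation:
    @staticmethod
    def _cohort_from_arrays(feat, cov, y):
        ids = pd.Index([f"s{i}" for i in range(len(y))], name="sample_id")
        return CohortTable(
            features=pd.DataFrame({"m": feat}, index=ids),
            covariates=pd.DataFrame(cov, index=ids),
            outcome=pd.Series(y.astype(int), index=ids))

    def test_orthogonal_adjustment_unchanged(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        c = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.4 * x - 1)))).astype(float)
        t = self._cohort_from_arrays(x, {"c": c}, y)
        plain = feature_association(t, "m")
        adj = feature_association(t, "m", ("c",))
        assert adj.odds_ratio == pytest.approx(plain.odds_ratio, rel=0.02)

    def test_mediator_collapses_conditional_or(self, rng):
        # chain: feature -> mediator -> outcome; conditioning on the mediator
        # removes the feature's association
        n = 6000
        x = rng.standard_normal(n)
        med = x + 0.3 * rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(1.2 * med - 1)))).astype(float)
        t = self._cohort_from_arrays(x, {"med": med}, y)
        plain = feature_association(t, "m")
        adj = feature_association(t, "m", ("med",))
        assert plain.odds_ratio > 1.8
        assert adj.odds_ratio == pytest.approx(1.0, abs=0.12)

    def test_ci_bracket_invariant(self, small_cohort):
        table, _ = standardise(impute_minimum(small_cohort))
        res = feature_association(table, "alpha")
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestQValues:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            qvalues([0.01, 0.02, 0.03], method="bh"), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert qvalues([0.2], method="bh")[0] == pytest.approx(0.2)

    def test_matches_bh_reference(self, rng):
        from scipy.stats import false_discovery_control
        p = rng.uniform(size=200)
        np.testing.assert_allclose(qvalues(p, method="bh"),
                                   false_discovery_control(p, method="bh"),
                                   atol=1e-12)

    def test_storey_scales_bh_by_pi0(self, rng):
        p = rng.uniform(size=500) ** 2  # enriched near 0
        m = p.size
        pi0 = np.clip(np.sum(p > 0.5) / (m * 0.5), 1 / m, 1.0)
        np.testing.assert_allclose(qvalues(p, method="storey"),
                                   np.clip(pi0 * qvalues(p, method="bh"), 0, 1),
                                   atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2,
                    max_size=60))
    def test_monotone_in_p(self, ps):
        q = qvalues(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
        assert np.all((np.asarray(q) > 0) & (np.asarray(q) <= 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            qvalues([])
        with pytest.raises(ValueError):
            qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            qvalues([1.5])


class TestAssociationScreen:
    def test_power_and_specificity(self):
        rng = np.random.default_rng(77)
        n, n_null, n_sig = 1500, 95, 5
        X = rng.standard_normal((n, n_null + n_sig))
        betas = np.log(1.8) * np.ones(n_sig)
        lp = X[:, :n_sig] @ betas - 1.0
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(int)
        ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        names = [f"sig{j}" for j in range(n_sig)] + [f"null{j}" for j in range(n_null)]
        table = CohortTable(
            features=pd.DataFrame(X, index=ids, columns=names),
            covariates=pd.DataFrame(index=ids),
            outcome=pd.Series(y, index=ids))
        table, _ = standardise(table)
        results = association_screen(table)[()]
        frame = screen_frame(results)
        sig = frame[frame["significant"]]["feature"].tolist()
        assert sum(f.startswith("sig") for f in sig) >= 4
        assert sum(f.startswith("null") for f in sig) <= 1

    def test_null_cohort_no_hits(self):
        config = SyntheticConfig(n_samples=400, n_progressors=100,
                                 n_targeted=0, n_untargeted=50,
                                 covariate_model={}, seed=21)
        table, _ = standardise(impute_minimum(generate_cohort(config)))
        frame = screen_frame(association_screen(table)[()])
        assert frame["significant"].sum() == 0

    def test_direction_labels(self, small_cohort):
        table, _ = standardise(impute_minimum(small_cohort))
        frame = screen_frame(association_screen(table)[()])
        alpha = frame.set_index("feature").loc["alpha"]
        beta = frame.set_index("feature").loc["beta"]
        assert alpha["direction"] == "positive"
        assert beta["direction"] == "negative"


class TestBaselineCharacteristics:
    def test_fisher_2x2_printed_value(self):
        from scipy.stats import fisher_exact
        p = fisher_exact([[27, 3], [190, 99]])[1]
        assert round(p, 2) == 0.01

    def test_welch_from_summary_printed_value(self):
        t, p = welch_from_summary(397, 48.22, 0.72, 146, 52.34, 0.99)
        assert p == pytest.approx(0.00089, rel=0.05)
        assert t < 0  # second group older

    def test_identical_groups(self):
        ids = pd.Index([f"s{i}" for i in range(40)], name="sample_id")
        vals = np.tile([1.0, 2.0], 20)
        table = CohortTable(
            features=pd.DataFrame({"f": np.zeros(40) + np.arange(40)},
                                  index=ids),
            covariates=pd.DataFrame({"grp": vals, "cont": np.tile(
                np.arange(20.0), 2)}, index=ids),
            outcome=pd.Series(np.r_[np.zeros(20, int), np.ones(20, int)],
                              index=ids))
        report = baseline_characteristics(
            table, {"grp": "categorical", "cont": "continuous"})
        fisher = report.set_index("variable").loc["grp"]
        welch = report.set_index("variable").loc["cont"]
        assert fisher["p_value"] == pytest.approx(1.0)
        assert welch["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_single_level_skipped(self):
        ids = pd.Index(["a", "b", "c", "d"], name="sample_id")
        table = CohortTable(
            features=pd.DataFrame({"f": [1.0, 2, 3, 4]}, index=ids),
            covariates=pd.DataFrame({"k": [1.0, 1, 1, 1]}, index=ids),
            outcome=pd.Series([0, 0, 1, 1], index=ids))
        report = baseline_characteristics(table, {"k": "categorical"})
        assert "skipped" in report.iloc[0]["note"]

    def test_rxc_monte_carlo_deterministic(self, rng):
        ids = pd.Index([f"s{i}" for i in range(90)], name="sample_id")
        table = CohortTable(
            features=pd.DataFrame({"f": rng.standard_normal(90)}, index=ids),
            covariates=pd.DataFrame(
                {"cat3": rng.choice([0.0, 1.0, 2.0], size=90)}, index=ids),
            outcome=pd.Series(rng.choice([0, 1], size=90), index=ids))
        a = baseline_characteristics(table, {"cat3": "categorical"},
                                     seed=5, n_draws=20_000)
        b = baseline_characteristics(table, {"cat3": "categorical"},
                                     seed=5, n_draws=20_000)
        assert a.iloc[0]["p_value"] == b.iloc[0]["p_value"]
        assert 0 < a.iloc[0]["p_value"] <= 1

    def test_default_typing(self, small_cohort):
        report = baseline_characteristics(small_cohort)
        by_var = report.set_index("variable")
        assert by_var.loc["sex", "test"] == "fisher"
        assert by_var.loc["age", "test"] == "welch"
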