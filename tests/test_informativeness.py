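"""Covariate screens, proportional-odds fitting, backward-AIC selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from scanqc import (CohortSpec, OrdinalQCModel, backward_eliminate_aic,
                    compare_models, covariate_screen, simulate_feature_cohort)
from scanqc.images import InputError
from scanqc.informativeness import FitError


def simulate_ordinal(rng, n, beta, cutpoints=(-1.0, 1.0)):
    """Draw (X, y) from the proportional-odds model itself."""
    beta = np.atleast_1d(beta)
    X = rng.standard_normal((n, beta.size))
    y = np.digitize(X @ beta + rng.logistic(size=n), cutpoints)
    cols = [f"x{i}" for i in range(beta.size)]
    return pd.DataFrame(X, columns=cols), y


class TestCovariateScreen:
    def test_bonferroni_multiplies_by_total_test_count(self):
        cohort, _ = simulate_feature_cohort(CohortSpec(seed=2))
        feats = [c for c in cohort.columns
                 if c not in ("site", "age", "sex", "MMSE", "amyloid", "APOE")][:10]
        screen = covariate_screen(cohort, feats)
        assert screen.n_tests == 60   # 10 features x 6 covariates
        row = screen.table.iloc[0]
        assert row.p_bonf == pytest.approx(min(1.0, row.p_raw * 60))

    def test_site_shift_detected_after_bonferroni(self):
        # additive site shift of 3 within-site SDs is found essentially always
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_per, sd = 50, 1.0
            rows = []
            for s in range(4):
                for _ in range(n_per):
                    rows.append({
                        "feat": rng.normal(3.0 * sd * s, sd), "site": f"s{s}",
                        "age": rng.uniform(50, 88), "sex": rng.choice(["F", "M"]),
                        "MMSE": rng.integers(24, 31), "amyloid": rng.integers(0, 2),
                        "APOE": rng.integers(0, 2)})
            screen = covariate_screen(pd.DataFrame(rows), ["feat"])
            site_row = screen.table.query("covariate == 'site'").iloc[0]
            hits += bool(site_row.significant)
        assert hits == 20

    def test_null_feature_p_values_are_uniform(self):
        # raw p for a covariate unrelated to the feature ~ U(0,1)
        from scipy import stats
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            n = 80
            df = pd.DataFrame({
                "feat": rng.normal(size=n), "site": rng.choice(["a", "b"], n),
                "age": rng.uniform(50, 88, n), "sex": rng.choice(["F", "M"], n),
                "MMSE": rng.integers(24, 31, n), "amyloid": rng.integers(0, 2, n),
                "APOE": rng.integers(0, 2, n)})
            screen = covariate_screen(df, ["feat"])
            pvals.append(screen.table.query("covariate == 'age'").iloc[0].p_raw)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_feature_skipped(self):
        cohort, _ = simulate_feature_cohort(CohortSpec(seed=3))
        cohort["flat"] = 1.0
        feats = ["flat", "SNR"]
        screen = covariate_screen(cohort, feats)
        assert set(screen.table.feature) == {"SNR"}

    def test_missing_covariate_column_rejected(self):
        cohort, _ = simulate_feature_cohort(CohortSpec(seed=3))
        with pytest.raises(InputError):
            covariate_screen(cohort.drop(columns=["MMSE"]), ["SNR"])

    def test_too_few_complete_rows_rejected(self):
        cohort, _ = simulate_feature_cohort(CohortSpec(seed=3))
        with pytest.raises(InputError):
            covariate_screen(cohort.head(5), ["SNR"])


class TestOrdinalModel:
    def test_recovers_generating_coefficient(self, rng):
        X, y = simulate_ordinal(rng, 4000, np.array([1.0]))
        res = OrdinalQCModel(y, X).fit()
        assert res.params["x0"] == pytest.approx(1.0, abs=0.15)
        assert res.odds_ratios["x0"] == pytest.approx(np.exp(res.params["x0"]))

    def test_two_level_labels_match_binary_logistic(self, rng):
        X, y = simulate_ordinal(rng, 1500, np.array([0.8, -0.5]), cutpoints=(0.0,))
        res = OrdinalQCModel(y, X).fit()
        logit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.params.values, logit.params[X.columns].values,
                                   atol=1e-6)
        assert res.llf == pytest.approx(logit.llf, abs=1e-6)

    def test_affine_predictor_rescaling_inverts_coefficient(self, rng):
        X, y = simulate_ordinal(rng, 1000, np.array([0.7]))
        base = OrdinalQCModel(y, X).fit()
        rescaled = X.copy()
        rescaled["x0"] = rescaled["x0"] * 4.0
        scaled = OrdinalQCModel(y, rescaled).fit()
        assert scaled.params["x0"] == pytest.approx(base.params["x0"] / 4.0, rel=1e-8)
        assert scaled.llf == pytest.approx(base.llf, abs=1e-8)
        assert scaled.aic == pytest.approx(base.aic, abs=1e-8)
        assert scaled.pvalues["x0"] == pytest.approx(base.pvalues["x0"], abs=1e-8)

    def test_aic_identity_holds(self, rng):
        X, y = simulate_ordinal(rng, 500, np.array([0.5, 0.1]))
        res = OrdinalQCModel(y, X).fit()
        assert res.aic == pytest.approx(-2 * res.llf + 2 * (2 + res.n_cutpoints))

    def test_string_labels_use_fixed_taxonomy_order(self, rng):
        X, y = simulate_ordinal(rng, 800, np.array([1.0]))
        names = np.array(["poor", "moderate", "good"])[y]
        res_str = OrdinalQCModel(names, X).fit()
        res_num = OrdinalQCModel(y, X).fit()
        assert res_str.params["x0"] == pytest.approx(res_num.params["x0"], rel=1e-6)
        assert res_str.label_levels == ("poor", "moderate", "good")

    def test_summary_has_table_shape(self, rng):
        X, y = simulate_ordinal(rng, 500, np.array([0.5, 0.1]))
        table = OrdinalQCModel(y, X).fit().summary()
        assert list(table.columns) == ["Parameter", "OddsRatio", "CI_low", "CI_high", "p"]
        assert (table.CI_low <= table.CI_high).all()

    def test_single_label_level_rejected(self, rng):
        X = pd.DataFrame({"x0": rng.standard_normal(50)})
        with pytest.raises(InputError):
            OrdinalQCModel(np.zeros(50, dtype=int), X)

    def test_complete_separation_raises_fit_error(self):
        x = np.linspace(-3, 3, 200)
        y = (x > 0).astype(int)
        with pytest.raises(FitError):
            OrdinalQCModel(y, pd.DataFrame({"x0": x})).fit()


class TestBackwardElimination:
    def test_reduced_aic_never_exceeds_full(self, rng):
        X, y = simulate_ordinal(rng, 600, np.array([0.8, 0.0, 0.0]))
        model = OrdinalQCModel(y, X)
        full = model.fit()
        reduced, log = backward_eliminate_aic(model)
        assert reduced.aic <= full.aic + 1e-9
        for step in log:
            assert step.aic_after < step.aic_before

    def test_informative_single_predictor_not_removed(self, rng):
        X, y = simulate_ordinal(rng, 1000, np.array([1.5]))
        reduced, log = backward_eliminate_aic(OrdinalQCModel(y, X))
        assert log == []
        assert reduced.feature_names == ["x0"]

    def test_pure_noise_single_predictor_reduces_to_null_model(self, rng):
        X = pd.DataFrame({"x0": rng.standard_normal(1000)})
        y = np.digitize(rng.logistic(size=1000), [-1.0, 1.0])
        model = OrdinalQCModel(y, X)
        reduced, log = backward_eliminate_aic(model)
        assert [s.removed for s in log] == ["x0"]
        assert reduced.feature_names == []
        assert reduced.llf == pytest.approx(model.null_llf())

    def test_noise_predictors_removed_before_informative_ones(self, rng):
        X, y = simulate_ordinal(rng, 2000, np.r_[np.full(4, 0.6), np.zeros(2)])
        reduced, log = backward_eliminate_aic(OrdinalQCModel(y, X))
        removed = {s.removed for s in log}
        assert removed <= {"x4", "x5"}
        assert {"x0", "x1", "x2", "x3"} <= set(reduced.feature_names)


class TestModelComparison:
    def test_identical_models_give_zero_lr_p_one(self, rng):
        X, y = simulate_ordinal(rng, 400, np.array([0.5]))
        res = OrdinalQCModel(y, X).fit()
        cmp = compare_models(res, res)
        assert cmp.lr == 0.0 and cmp.pvalue == 1.0 and cmp.df == 0

    def test_lr_nonnegative_and_df_counts_dropped_features(self, rng):
        X, y = simulate_ordinal(rng, 800, np.array([0.8, 0.0]))
        full = OrdinalQCModel(y, X).fit()
        reduced = OrdinalQCModel(y, X[["x0"]]).fit()
        cmp = compare_models(full, reduced)
        assert cmp.lr >= 0 and cmp.df == 1 and 0 <= cmp.pvalue <= 1

    def test_non_nested_models_rejected(self, rng):
        X, y = simulate_ordinal(rng, 400, np.array([0.5, 0.2]))
        a = OrdinalQCModel(y, X[["x0"]]).fit()
        b = OrdinalQCModel(y, X[["x1"]]).fit()
        with pytest.raises(InputError):
            compare_models(a, b)

    def test_different_observation_sets_rejected(self, rng):
        X, y = simulate_ordinal(rng, 400, np.array([0.5]))
        full = OrdinalQCModel(y, X).fit()
        reduced = OrdinalQCModel(y[:300], X.head(300)).fit()
        with pytest.raises(InputError):
            compare_models(full, reduced)
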