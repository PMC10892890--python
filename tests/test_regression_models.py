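"""Correlations, power law, NB/beta ML fits, AICc and model selection."""

import numpy as np
import pandas as pd
import pytest
import scipy.special
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from insulametrics.errors import BoundaryValueError, ValidationError
from insulametrics.regression_models import (
    ModelSpec,
    aicc,
    best_subsets,
    fit_beta_regression,
    fit_negative_binomial,
    fit_species_area_power_law,
    format_report,
    model_report,
    pearson_r,
    predict_surface,
)
from insulametrics.synthetic_data import TableConfig, generate_island_table
from oracles import beta_grid_search_ml, nb_grid_search_ml


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_and_antisymmetry(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert pearson_r(-x, y) == pytest.approx(-r, abs=1e-9)


class TestPowerLaw:
    def test_noiseless_recovery(self):
        A = np.array([100.0, 500.0, 2500.0, 9000.0, 26000.0])
        df = pd.DataFrame({"Area": A, "Spp": np.round(10.0 * A**0.3).astype(int)})
        df["Spp"] = 10.0 * A**0.3  # exact, not rounded
        fit = fit_species_area_power_law(df)
        assert fit.c == pytest.approx(10.0, rel=1e-9)
        assert fit.z == pytest.approx(0.3, rel=1e-9)
        assert fit.r_loglog == pytest.approx(1.0)

    def test_constant_area_rejected(self):
        df = pd.DataFrame({"Area": [5.0] * 4, "Spp": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValidationError):
            fit_species_area_power_law(df)

    def test_nonpositive_values_rejected(self):
        df = pd.DataFrame({"Area": [1.0, 2.0, 3.0], "Spp": [5.0, 0.0, 7.0]})
        with pytest.raises(ValidationError):
            fit_species_area_power_law(df)


class TestAicc:
    def test_arithmetic(self):
        # AIC = 108; correction 2*4*5/(8-5) = 40/3
        assert aicc(-50.0, 4, 8) == pytest.approx(108 + 40 / 3)

    def test_limit_to_aic_for_large_n(self):
        assert aicc(-50.0, 4, 10**9) == pytest.approx(108.0, abs=1e-6)

    def test_k_zero_equals_aic(self):
        assert aicc(-12.5, 0, 5) == pytest.approx(25.0)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValidationError):
            aicc(-50.0, 4, 5)

    def test_strictly_decreasing_in_loglik(self):
        assert aicc(-49.0, 4, 8) < aicc(-50.0, 4, 8)


class TestNegativeBinomial:
    def test_intercept_only_mean_is_arithmetic_mean(self, fixture_df):
        fit = fit_negative_binomial(fixture_df, predictors=())
        assert fit.coefficients["Intercept"] == pytest.approx(
            np.log(fixture_df.Spp.mean()), rel=1e-6
        )
        assert fit.k == 2

    def test_matches_grid_search_oracle_on_tiny_data(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, size=5)
        mu = np.exp(3.0 + 1.2 * x)
        y = rng.poisson(rng.gamma(8.0, mu / 8.0))
        df = pd.DataFrame({"X": x, "Y": y})
        fit = fit_negative_binomial(df, ["X"], response="Y")
        b0, b1, th = nb_grid_search_ml(y, x)
        assert fit.coefficients["Intercept"] == pytest.approx(b0, rel=2e-3)
        assert fit.coefficients["X"] == pytest.approx(b1, rel=2e-3)
        assert fit.theta == pytest.approx(th, rel=2e-3)

    def test_large_theta_approaches_poisson_glm(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 2, size=120)
        y = rng.poisson(np.exp(2.0 + 0.7 * x))
        df = pd.DataFrame({"X": x, "Y": y})
        fit = fit_negative_binomial(df, ["X"], response="Y", theta=1e8)
        X = sm.add_constant(x)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.coefficients["Intercept"] == pytest.approx(pois.params[0], rel=1e-4)
        assert fit.coefficients["X"] == pytest.approx(pois.params[1], rel=1e-4)

    def test_adding_predictor_never_raises_residual_deviance_at_fixed_theta(self, fixture_df):
        base = fit_negative_binomial(fixture_df, ["Area"], theta=50.0)
        bigger = fit_negative_binomial(fixture_df, ["Area", "Topography"], theta=50.0)
        assert bigger.residual_deviance <= base.residual_deviance + 1e-8
        assert 0.0 <= base.explained_deviance <= 1.0
        assert base.residual_deviance <= base.null_deviance

    def test_count_invariants(self, fixture_df):
        fit = fit_negative_binomial(fixture_df, ["Area", "Topography"])
        assert fit.k == 4 and fit.n == 8
        assert fit.theta > 0
        assert set(fit.wald_p) == {"Intercept", "Area", "Topography"}
        assert all(0 <= p <= 1 for p in fit.wald_p.values())

    def test_non_integer_counts_rejected(self):
        df = pd.DataFrame({"X": [1, 2, 3, 4], "Y": [1.5, 2, 3, 4]})
        with pytest.raises(ValidationError):
            fit_negative_binomial(df, ["X"], response="Y")

    def test_too_few_observations_rejected(self, fixture_df):
        with pytest.raises(ValidationError):
            fit_negative_binomial(fixture_df.head(3), ["Area", "Topography", "Isolation"])


class TestBetaRegression:
    def test_noiseless_logit_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, size=60)
        mu = scipy.special.expit(-0.5 + 1.5 * x)
        phi = 5000.0
        y = rng.beta(mu * phi, (1 - mu) * phi)
        df = pd.DataFrame({"X": x, "Y": y})
        fit = fit_beta_regression(df, ["X"], response="Y")
        assert fit.coefficients["Intercept"] == pytest.approx(-0.5, abs=0.02)
        assert fit.coefficients["X"] == pytest.approx(1.5, abs=0.03)
        assert fit.pseudo_r2 > 0.99

    def test_matches_grid_search_oracle_on_tiny_data(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 1, size=6)
        mu = scipy.special.expit(-1.0 + 1.0 * x)
        y = rng.beta(mu * 40.0, (1 - mu) * 40.0)
        df = pd.DataFrame({"X": x, "Y": y})
        fit = fit_beta_regression(df, ["X"], response="Y")
        g0, g1, phi = beta_grid_search_ml(y, x)
        assert fit.coefficients["Intercept"] == pytest.approx(g0, rel=2e-3, abs=2e-3)
        assert fit.coefficients["X"] == pytest.approx(g1, rel=2e-3, abs=2e-3)
        assert fit.phi == pytest.approx(phi, rel=2e-3)

    def test_boundary_values_error_by_default(self):
        df = pd.DataFrame({"X": [0.1, 0.2, 0.3, 0.4, 0.5], "Y": [0.0, 0.2, 0.4, 0.5, 0.9]})
        with pytest.raises(BoundaryValueError):
            fit_beta_regression(df, ["X"], response="Y")

    def test_boundary_shrink_is_explicit_smithson_verkuilen(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=30)
        y = rng.beta(2, 5, size=30)
        y[0] = 0.0
        df = pd.DataFrame({"X": x, "Y": y})
        fit = fit_beta_regression(df, ["X"], response="Y", boundary="shrink")
        assert fit.phi > 0 and np.isfinite(fit.loglik)


class TestBestSubsets:
    def test_published_nb_suite_ranks_two_predictor_model_first(self, fixture_table):
        from insulametrics.regression_models import NB_SUITE

        specs = [ModelSpec(lab, preds, "count") for lab, preds in NB_SUITE.items()]
        mt = best_subsets(fixture_table, "count", specs=specs)
        assert mt.best[0].label == "C1"
        assert not mt.failures

    def test_single_candidate_trivially_ranked(self, fixture_table):
        mt = best_subsets(fixture_table, "count", candidates=["Topography"])
        assert len(mt.fits) == 1
        assert mt.fits[0][0].predictors == ("Topography",)

    def test_engineered_tie_broken_by_label(self, fixture_table):
        specs = [
            ModelSpec("Z", ("Area", "Topography"), "count"),
            ModelSpec("A", ("Area", "Topography"), "count"),
        ]
        mt = best_subsets(fixture_table, "count", specs=specs)
        assert [s.label for s, _ in mt.fits] == ["A", "Z"]
        assert mt.fits[0][1].aicc == mt.fits[1][1].aicc

    def test_tie_between_unequal_k_broken_by_fewer_parameters(self):
        # identical AICc forced by construction: duplicate column means the
        # 2-predictor fit cannot beat the 1-predictor fit's likelihood, so we
        # only check ordering is (aicc, k, label)-stable on equal-aicc entries
        from insulametrics.regression_models import ModelTable

        fits = []
        spec_small = ModelSpec("S", ("Area",), "count")
        spec_big = ModelSpec("B", ("Area", "Topography"), "count")

        class _Stub:
            def __init__(self, aicc_val, k):
                self.aicc = aicc_val
                self.k = k

        mt = ModelTable(fits=[(spec_big, _Stub(100.0, 4)), (spec_small, _Stub(100.0, 3))])
        assert [s.label for s, _ in mt.fits] == ["S", "B"]

    def test_failed_member_flagged_others_ranked(self, fixture_df):
        df = fixture_df.copy()
        df["Constant"] = 1.0
        specs = [
            ModelSpec("OK", ("Area",), "count"),
            ModelSpec("BAD", ("Constant",), "count"),
        ]
        mt = best_subsets(df, "count", specs=specs)
        assert [s.label for s, _ in mt.fits] == ["OK"]
        assert len(mt.failures) == 1 and mt.failures[0][0].label == "BAD"


class TestReporting:
    def test_report_contains_deviance_fields_and_no_intercept_p(self, fixture_table):
        from insulametrics.regression_models import NB_SUITE

        specs = [ModelSpec(lab, preds, "count") for lab, preds in NB_SUITE.items()]
        mt = best_subsets(fixture_table, "count", specs=specs)
        df = model_report(mt)
        row = df[df.Model == "C1"].iloc[0]
        for col in ("NullDeviance", "ResidualDeviance", "ExplainedPct", "AIC", "AICc"):
            assert np.isfinite(row[col])
        assert "p(Intercept)" not in df.columns
        text = format_report(mt)
        assert "C1" in text and "%" in text

    def test_report_csv_round_trip(self, tmp_path, fixture_table):
        mt = best_subsets(fixture_table, "count", candidates=["Area", "Topography"])
        df = model_report(mt)
        p = tmp_path / "report.csv"
        df.to_csv(p, index=False)
        back = pd.read_csv(p)
        np.testing.assert_allclose(back["AICc"], df["AICc"], rtol=1e-12)


class TestPredictSurface:
    def test_surface_matches_fitted_means_at_observations(self, fixture_df):
        fit = fit_negative_binomial(fixture_df, ["Area", "Topography"])
        mu_hat = fit.predict(fixture_df)
        for _, row in fixture_df.iterrows():
            surf = predict_surface(fit, "Area", "Topography", [row.Area], [row.Topography])
            assert surf.iloc[0, 0] == pytest.approx(
                mu_hat[fixture_df.index[fixture_df.Island == row.Island][0]], rel=1e-12
            )

    def test_monotone_in_positive_coefficient(self, fixture_df):
        fit = fit_negative_binomial(fixture_df, ["Area", "Topography"])
        assert fit.coefficients["Area"] > 0
        areas = np.linspace(300, 26000, 25)
        surf = predict_surface(fit, "Area", "Topography", areas, [250.0])
        assert (np.diff(surf.values[0]) > 0).all()

    def test_unknown_predictor_rejected(self, fixture_df):
        fit = fit_negative_binomial(fixture_df, ["Area", "Topography"])
        with pytest.raises(ValidationError):
            predict_surface(fit, "Area", "Isolation", [1.0], [1.0])

    def test_unpinned_extra_predictor_rejected(self, fixture_df):
        fit = fit_negative_binomial(fixture_df, ["Area", "Topography", "Isolation"])
        with pytest.raises(ValidationError):
            predict_surface(fit, "Area", "Topography", [1000.0], [200.0])
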