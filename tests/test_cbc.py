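"""CBC log-ratios, paired ratio change and logistic response models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from tnfblood import simulate
from tnfblood.cbc import (
    SeparationError,
    cbc_log_ratios,
    genotype_association,
    logistic_fit,
    paired_ratio_change,
    response_model,
)


class TestCbcLogRatios:
    def test_arithmetic(self):
        nlr, nwr, lwr = cbc_log_ratios(4.0, 2.0, 8.0)
        assert nlr == pytest.approx(np.log(2))
        assert nwr == pytest.approx(np.log(0.5))
        assert lwr == pytest.approx(np.log(0.25))

    def test_equal_counts_zero_nlr(self):
        nlr, _, _ = cbc_log_ratios(3.0, 3.0, 7.0)
        assert nlr == pytest.approx(0.0)

    @given(
        n=st.floats(0.1, 50),
        l=st.floats(0.1, 50),
        w=st.floats(0.1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_identity_nwr_minus_lwr_is_nlr(self, n, l, w):
        nlr, nwr, lwr = cbc_log_ratios(n, l, w)
        assert abs((nwr - lwr) - nlr) < 1e-12

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            cbc_log_ratios(0.0, 1.0, 2.0)


class TestPairedRatioChange:
    def test_degenerate_constant_ratio(self):
        idx = [f"s{i}" for i in range(5)]
        bl = pd.Series(1.0, index=idx)
        mo3 = pd.Series(0.87, index=idx)
        est, ci, p = paired_ratio_change(bl, mo3)
        assert est == pytest.approx(87.0)
        assert ci == (est, est)
        assert p == 0.0

    def test_symmetric_ratios_are_null(self):
        idx = [f"s{i}" for i in range(6)]
        bl = pd.Series(1.0, index=idx)
        mo3 = pd.Series(np.exp([0.1, -0.1, 0.2, -0.2, 0.05, -0.05]), index=idx)
        est, _, p = paired_ratio_change(bl, mo3)
        assert est == pytest.approx(100.0)
        assert p >= 0.9

    def test_unpaired_subjects_dropped_with_warning(self):
        bl = pd.Series([1.0, 1.0, 1.0, 1.0], index=["a", "b", "c", "d"])
        mo3 = pd.Series([0.9, 0.9, 0.9], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="unpaired"):
            est, _, _ = paired_ratio_change(bl, mo3)
        assert est == pytest.approx(90.0)

    def test_too_few_pairs_rejected(self):
        s = pd.Series([1.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            paired_ratio_change(s, s)


class TestLogisticFit:
    def test_saturated_2x2_matches_cross_product_odds_ratio(self):
        # a=30 (y=1,x=1), b=10 (y=0,x=1), c=15 (y=1,x=0), d=20 (y=0,x=0)
        x = np.r_[np.ones(40), np.zeros(35)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(15), np.zeros(20)]
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.odds_ratio("x") == pytest.approx(4.0, abs=1e-6)

    def test_matches_newton_oracle_one_covariate(self):
        # independent Newton-Raphson on the 1-covariate log-likelihood
        rng = np.random.default_rng(70)
        x = rng.normal(size=300)
        y = rng.binomial(1, expit(0.3 + 0.8 * x))
        X = np.column_stack([np.ones(300), x])
        beta = np.zeros(2)
        for _ in range(50):
            mu = expit(X @ beta)
            W = mu * (1 - mu)
            step = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - mu))
            beta += step
            if np.abs(step).max() < 1e-12:
                break
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.table.loc["x", "coef"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.table.loc["const", "coef"] == pytest.approx(beta[0], abs=1e-6)

    def test_intercept_only_recovers_outcome_mean(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = logistic_fit(pd.DataFrame(index=range(100)), y)
        assert expit(fit.table.loc["const", "coef"]) == pytest.approx(0.3, abs=1e-8)

    def test_independent_covariate_near_null(self):
        rng = np.random.default_rng(71)
        x = rng.normal(size=400)
        y = rng.binomial(1, 0.5, size=400)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.odds_ratio("x") == pytest.approx(1.0, abs=0.3)
        assert fit.table.loc["x", "p"] > 0.05

    def test_complete_separation_reported(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        y = x.copy()
        with pytest.raises(SeparationError):
            logistic_fit(pd.DataFrame({"x": x}), y)

    def test_constant_outcome_reported(self):
        with pytest.raises(SeparationError):
            logistic_fit(pd.DataFrame({"x": np.arange(10.0)}), np.ones(10))

    def test_wald_ci_brackets_odds_ratio(self):
        rng = np.random.default_rng(72)
        x = rng.normal(size=200)
        y = rng.binomial(1, expit(0.2 * x))
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        lo, hi = fit.ci("x")
        assert lo < fit.odds_ratio("x") < hi


@pytest.fixture(scope="module")
def population():
    cbc, labels, covs, truth = simulate.generate_cbc_population(2000, 1.2, seed=73)
    meta = covs.copy()
    meta["response"] = labels
    return cbc, meta, truth


class TestResponseModel:
    def test_recovers_target_odds_ratio(self, population):
        cbc, meta, truth = population
        fit, _ = response_model(cbc, meta, ratio="nlr", adjusted=True)
        lo, hi = fit.ci("log_nlr")
        assert lo < np.exp(truth.nlr_log_or_slope) < hi

    def test_nlr_and_lwr_signs_oppose_when_wbc_is_sum(self):
        rng = np.random.default_rng(74)
        n = 500
        neut = rng.lognormal(1.4, 0.4, n)
        lymph = rng.lognormal(0.7, 0.3, n)
        cbc = pd.DataFrame(
            {"neutrophils": neut, "lymphocytes": lymph, "wbc": neut + lymph},
            index=[f"s{i}" for i in range(n)],
        )
        log_nlr = np.log(neut / lymph)
        y = rng.binomial(1, expit(0.4 * (log_nlr - log_nlr.mean())))
        meta = pd.DataFrame(
            {"response": np.where(y == 1, "good", "none")}, index=cbc.index
        )
        fit_nlr, _ = response_model(cbc, meta, ratio="nlr")
        fit_lwr, _ = response_model(cbc, meta, ratio="lwr")
        assert np.sign(fit_nlr.table.loc["log_nlr", "coef"]) == -np.sign(
            fit_lwr.table.loc["log_lwr", "coef"]
        )

    def test_constant_outcome_reported_as_separation(self, population):
        cbc, meta, _ = population
        constant = meta.copy()
        constant["response"] = "good"
        with pytest.raises(SeparationError):
            response_model(cbc, constant, ratio="nlr")

    def test_missing_covariates_listwise_deleted(self, population):
        cbc, meta, _ = population
        meta2 = meta.copy()
        meta2.loc[meta2.index[:25], "mhaq"] = np.nan
        fit, _ = response_model(cbc, meta2, ratio="nlr", adjusted=True)
        assert fit.n_dropped == 25
        assert fit.n == len(cbc) - 25

    def test_or_transforms_under_covariate_rescaling(self, population):
        # affine rescaling of a covariate rescales its coefficient; the
        # log-ratio OR is essentially unchanged
        cbc, meta, _ = population
        scaled = meta.copy()
        scaled["age10"] = scaled["age10"] * 10.0  # age in years instead
        fit, _ = response_model(cbc, meta, ratio="nlr", adjusted=True)
        fit_s, _ = response_model(cbc, scaled, ratio="nlr", adjusted=True)
        assert fit_s.table.loc["age10", "coef"] == pytest.approx(
            fit.table.loc["age10", "coef"] / 10.0, rel=1e-5
        )
        assert fit_s.odds_ratio("log_nlr") == pytest.approx(
            fit.odds_ratio("log_nlr"), rel=1e-5
        )

    def test_forest_export_columns(self, population):
        cbc, meta, _ = population
        _, forest = response_model(cbc, meta, ratio="nwr", adjusted=True)
        assert list(forest.columns) == ["term", "or", "ci_low", "ci_high", "p"]
        assert "log_nwr" in set(forest["term"])


class TestGenotypeAssociation:
    def test_proportional_rows_near_null(self):
        _, p = genotype_association([[40, 20, 10], [80, 40, 20]])
        assert p > 0.99

    def test_skewed_table_detected(self):
        _, p = genotype_association([[50, 10, 5], [10, 30, 40]])
        assert p < 0.01

    def test_pooling_identical_tables_increases_evidence(self):
        t = [[20, 10], [12, 18]]
        _, p_single = genotype_association(t)
        _, p_pooled = genotype_association([t, t], pool=True)
        assert p_pooled < p_single

    def test_multiple_tables_require_pool_flag(self):
        t = [[20, 10], [12, 18]]
        with pytest.raises(ValueError):
            genotype_association([t, t])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            genotype_association([[0, 0], [5, 7]])
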