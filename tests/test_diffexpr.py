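"""Precision-weighted linear modelling, moderation and FDR control."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tnfblood import simulate
from tnfblood.diffexpr import (
    DesignSpec,
    bh_fdr,
    ebayes_moderate,
    estimate_variance_prior,
    fit_weighted_lm,
    log_cpm,
    run_differential,
    voom_weights,
)


class TestLogCpm:
    def test_closed_form_zero_count(self):
        counts = pd.DataFrame({"s": [0, 10**6]}, index=["g0", "g1"])
        y = log_cpm(counts, prior_count=0.5)
        assert y.loc["g0", "s"] == pytest.approx(
            np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-9
        )

    def test_scale_invariance(self):
        # exact up to the pseudocount, which shrinks with depth
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(30, 4)))
        assert np.allclose(
            log_cpm(counts).values, log_cpm(counts * 2).values, atol=0.02
        )

    def test_single_gene_library_limit(self):
        counts = pd.DataFrame({"s": [10**6]})
        assert log_cpm(counts).iloc[0, 0] == pytest.approx(np.log2(1e6), abs=1e-4)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(pd.DataFrame({"s": [0, 0]}))


class TestVoomWeights:
    def test_homoscedastic_input_gives_flat_weights(self):
        rng = np.random.default_rng(1)
        y = pd.DataFrame(rng.normal(8, 1, size=(300, 12)))
        X = np.ones((12, 1))
        w = voom_weights(y, X)
        assert w.values.std() / w.values.mean() < 0.3

    def test_weights_track_decreasing_variance_trend(self):
        rng = np.random.default_rng(2)
        means = np.linspace(2, 12, 200)
        sds = np.linspace(2.0, 0.3, 200)
        y = pd.DataFrame(means[:, None] + rng.normal(0, sds[:, None], (200, 12)))
        w = voom_weights(y, np.ones((12, 1)))
        rho = stats.spearmanr(means, w.values.mean(axis=1)).statistic
        assert rho > 0.8

    def test_shape_and_positivity(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(40, size=(100, 8)))
        y = log_cpm(counts)
        w = voom_weights(y, np.ones((8, 1)), lib_size=counts.sum(0).to_numpy())
        assert w.shape == y.shape and (w.values > 0).all()

    def test_constant_input_rejected(self):
        y = pd.DataFrame(np.ones((50, 6)))
        with pytest.raises(ValueError):
            voom_weights(y, np.ones((6, 1)))


class TestFitWeightedLm:
    def test_unit_weights_recover_group_mean_difference(self):
        y = pd.DataFrame([[1.0, 2.0, 5.0, 7.0]], index=["g"])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = fit_weighted_lm(y, X, coef_names=["intercept", "grp"])
        assert fit.coefficients.loc["g", "grp"] == pytest.approx(4.5)

    def test_matches_normal_equations_oracle(self):
        # independent direct solve of the weighted normal equations
        rng = np.random.default_rng(4)
        y = pd.DataFrame(rng.normal(size=(5, 4)))
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        W = np.diag([4.0, 4.0, 1.0, 1.0])
        weights = pd.DataFrame(
            np.tile(np.array([4.0, 4.0, 1.0, 1.0]), (5, 1)),
            index=y.index,
            columns=y.columns,
        )
        fit = fit_weighted_lm(y, X, weights, coef_names=["intercept", "grp"])
        for g in y.index:
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y.loc[g].to_numpy())
            assert np.allclose(
                fit.coefficients.loc[g].to_numpy(), beta, atol=1e-10
            )

    def test_zero_residual_df_flagged(self):
        y = pd.DataFrame(np.random.default_rng(5).normal(size=(3, 2)))
        X = np.column_stack([np.ones(2), [0, 1]])
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_weighted_lm(y, X)

    def test_rank_deficiency_names_columns(self):
        y = pd.DataFrame(np.random.default_rng(6).normal(size=(3, 6)))
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1], [0, 0, 0, 2, 2, 2]])
        with pytest.raises(ValueError, match="dup"):
            fit_weighted_lm(y, X, coef_names=["intercept", "grp", "dup"])


@pytest.fixture(scope="module")
def two_group_fit():
    rng = np.random.default_rng(7)
    y = pd.DataFrame(rng.normal(0, 1, size=(50, 12)))
    X = np.column_stack([np.ones(12), np.r_[np.zeros(6), np.ones(6)]])
    return y, fit_weighted_lm(y, X, coef_names=["intercept", "grp"])


class TestEbayesModerate:
    def test_d0_zero_limit_equals_classical_t(self, two_group_fit):
        y, fit = two_group_fit
        table = ebayes_moderate(fit, "grp", prior=(0.0, 1.0))
        for g in y.index:
            t_classic = stats.ttest_ind(
                y.loc[g][6:], y.loc[g][:6], equal_var=True
            ).statistic
            assert table.loc[g, "t"] == pytest.approx(t_classic, abs=1e-8)

    def test_d0_infinite_limit_pools_all_variances(self, two_group_fit):
        _, fit = two_group_fit
        table = ebayes_moderate(fit, "grp", prior=(np.inf, 0.5))
        assert np.allclose(table["s2_post"], 0.5)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        y = pd.DataFrame(rng.normal(0, 1, size=(1000, 16)))
        X = np.column_stack([np.ones(16), np.r_[np.zeros(8), np.ones(8)]])
        fit = fit_weighted_lm(y, X, coef_names=["intercept", "grp"])
        table = ebayes_moderate(fit, "grp")
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01

    def test_prior_estimation_recovers_heterogeneous_variances(self):
        # features drawn with scaled inverse-chi-square variances: the
        # moment estimator should find a finite prior df
        rng = np.random.default_rng(9)
        d0_true, s02 = 8.0, 1.0
        n_feat, df = 2000, 10
        s2_true = d0_true * s02 / stats.chi2.rvs(d0_true, size=n_feat, random_state=1)
        s2_obs = s2_true * stats.chi2.rvs(df, size=n_feat, random_state=2) / df
        d0_hat, s02_hat = estimate_variance_prior(s2_obs, df)
        assert 0.5 * d0_true < d0_hat < 2 * d0_true
        assert s02_hat == pytest.approx(s02, rel=0.3)

    def test_nonfinite_variances_rejected(self):
        with pytest.raises(ValueError):
            estimate_variance_prior(np.array([1.0, np.nan]), 5)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2] * 7), 0.2)

    def test_matches_naive_definition(self):
        # q_i = min over j with p_j >= p_i of p_j * n / rank_j
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        n = p.size
        order = np.argsort(p)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        naive = np.array(
            [min(min(p[j] * n / ranks[j] for j in range(n) if p[j] >= p[i]), 1.0)
             for i in range(n)]
        )
        assert np.allclose(bh_fdr(p), naive, atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])


class TestRunDifferential:
    def test_neutrophil_markers_depleted_at_mo3(self, ref600, cohort_pair, mo3_spec):
        (counts, meta, _, truth), _ = cohort_pair
        table = run_differential(counts, meta, mo3_spec, is_counts=True)
        neut_markers = [
            g for g, ct in truth.gene_assignment.items() if ct == "neutrophils"
        ]
        neut_effects = table.loc[table.index.intersection(neut_markers), "effect"]
        other = table.loc[~table.index.isin(neut_markers), "effect"]
        # designed 13% neutrophil reduction: markers shift down vs the rest
        assert neut_effects.mean() < other.mean() - 0.05
        sig_down = table[(table["q"] < 0.05) & (table["effect"] < 0)]
        if len(sig_down) >= 10:
            frac_marker = sig_down.index.isin(neut_markers).mean()
            assert frac_marker > len(neut_markers) / len(table)

    def test_label_permutation_destroys_signal(self, cohort_pair, mo3_spec):
        (counts, meta, _, _), _ = cohort_pair
        rng = np.random.default_rng(12)
        shuffled = meta.copy()
        # permute visit labels within subject: treatment signal should vanish
        for subj in shuffled["subject"].unique():
            idx = shuffled.index[shuffled["subject"] == subj]
            if rng.random() < 0.5:
                shuffled.loc[idx, "visit"] = shuffled.loc[idx, "visit"].values[::-1]
        table = run_differential(counts, shuffled, mo3_spec, is_counts=True)
        assert (table["q"] < 0.05).mean() < 0.07

    def test_contrast_with_too_few_samples_rejected(self, ref600, mo3_spec):
        params = simulate.GeneratorParams(n_subjects_gr=2, n_subjects_nr=2, seed=13)
        counts, meta, _, _ = simulate.generate_cohort(params, ref600)
        keep = meta.index[:3]  # drop one visit of one subject
        with pytest.raises(ValueError):
            run_differential(
                counts[list(keep[:1])], meta.loc[keep[:1]], mo3_spec
            )

    def test_deterministic_given_fixed_input(self, cohort_pair, gr_spec):
        (counts, meta, _, _), _ = cohort_pair
        t1 = run_differential(counts, meta, gr_spec, is_counts=True)
        t2 = run_differential(counts, meta, gr_spec, is_counts=True)
        pd.testing.assert_frame_equal(t1, t2)


class TestAgainstLimmaOracle:
    """Independent cross-check of the whole chain against R limma-voom."""

    def test_agrees_with_limma_voom_on_small_matrix(self, tmp_path):
        rng = np.random.default_rng(14)
        mu = rng.lognormal(4, 1, size=120)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 5 / (5 + mu[:, None]), size=(120, 12)),
            index=[f"g{i}" for i in range(120)],
            columns=[f"s{j}" for j in range(12)],
        )
        counts += 1  # keep every gene above the expression filter
        group = np.r_[np.zeros(6), np.ones(6)]
        counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        rscript = tmp_path / "oracle.R"
        rscript.write_text(
            """
            suppressMessages(library(limma))
            counts <- as.matrix(read.delim("%s", row.names=1))
            design <- cbind(1, c(rep(0,6), rep(1,6)))
            v <- voom(counts, design)
            fit <- eBayes(lmFit(v, design))
            write.csv(data.frame(coef=fit$coefficients[,2], t=fit$t[,2],
                                 p=fit$p.value[,2]), "%s")
            """
            % (tmp_path / "counts.tsv", tmp_path / "limma.csv")
        )
        subprocess.run(
            ["Rscript", str(rscript)], check=True, capture_output=True
        )
        oracle = pd.read_csv(tmp_path / "limma.csv", index_col=0)

        meta = pd.DataFrame(
            {
                "visit": ["BL"] * 12,
                "response": np.where(group == 1, "good", "none"),
                "subject": counts.columns,
            },
            index=counts.columns,
        )
        spec = DesignSpec(contrast="GR-NR", paired=False)
        mine = run_differential(counts, meta, spec, is_counts=True)
        shared = mine.index.intersection(oracle.index)
        assert len(shared) >= 115  # low-expression filter may drop a few
        # coefficients agree closely; t/p to the extent the lowess
        # implementations match
        assert np.corrcoef(mine.loc[shared, "effect"], oracle.loc[shared, "coef"])[
            0, 1
        ] > 0.999
        assert np.abs(
            mine.loc[shared, "effect"] - oracle.loc[shared, "coef"]
        ).max() < 0.05
        assert np.corrcoef(mine.loc[shared, "t"], oracle.loc[shared, "t"])[0, 1] > 0.98
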