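"""Precision-weighted differential expression with empirical-Bayes moderation.

The modelling chain applied uniformly to RNA counts and protein intensities:

1. counts -> log2 counts-per-million with a pseudocount (:func:`log_cpm`);
2. a mean-variance trend fitted on sqrt residual standard deviations versus
   average log-count, turned into per-observation precision weights
   (:func:`voom_weights`);
3. per-feature weighted least squares on an arbitrary design
   (:func:`fit_weighted_lm`);
4. variance shrinkage toward a common prior by closed-form method of
   moments on log residual variances, yielding moderated t-statistics
   (:func:`ebayes_moderate`);
5. Benjamini-Hochberg step-up FDR (:func:`bh_fdr`).

Protein intensities (already log scale) skip steps 1-2 and use unit
weights.  :func:`run_differential` wires the chain for the two contrasts of
the study: the paired month-3 minus baseline treatment effect (with subject
fixed effects) and the responder minus non-responder baseline difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess


# ---------------------------------------------------------------------------
# log-CPM
# ---------------------------------------------------------------------------

def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: ``log2((c + prior) / (lib + 2*prior) * 1e6)``."""
    c = counts.to_numpy(dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = c.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    y = np.log2((c + prior_count) / (lib + 2 * prior_count) * 1e6)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# precision weights from the mean-variance trend
# ---------------------------------------------------------------------------

def voom_weights(
    logcpm: pd.DataFrame,
    design: np.ndarray,
    lib_size: np.ndarray | None = None,
    span: float = 0.5,
) -> pd.DataFrame:
    """Per-observation precision weights from the fitted mean-variance trend.

    Residual standard deviations of a per-feature least-squares fit are
    square-rooted and regressed by lowess (span 0.5) on average log2 count;
    the trend evaluated at each observation's fitted log-count gives a
    predicted sqrt-SD whose inverse fourth power is the weight.  When
    ``lib_size`` is ``None`` the trend is fitted on the log-CPM scale
    directly (appropriate for intensity data).
    """
    y = logcpm.to_numpy(dtype=float)
    n_feat, n_samp = y.shape
    X = np.asarray(design, dtype=float)
    df_resid = n_samp - np.linalg.matrix_rank(X)
    if df_resid < 2:
        raise ValueError("need >= 2 residual degrees of freedom")

    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    if np.allclose(sigma, 0):
        raise ValueError("all features constant after fitting the design")

    amean = y.mean(axis=1)
    if lib_size is not None:
        offset = np.mean(np.log2(np.asarray(lib_size, dtype=float) + 1.0)) - np.log2(1e6)
        sx = amean + offset
        fitted_logcount = fitted + (
            np.log2(np.asarray(lib_size, dtype=float) + 1.0) - np.log2(1e6)
        )
    else:
        sx = amean
        fitted_logcount = fitted
    sy = np.sqrt(sigma)

    ok = sigma > 0
    trend = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)
    w = pred_sqrt_sd**-4.0
    if not np.all(np.isfinite(w)) or (w <= 0).any():
        raise ValueError("non-finite or non-positive weights")
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


# ---------------------------------------------------------------------------
# weighted least squares per feature
# ---------------------------------------------------------------------------

@dataclass
class LMFit:
    """Per-feature weighted least-squares results."""

    coefficients: pd.DataFrame  # features x coefficients
    stdev_unscaled: pd.DataFrame  # sqrt of diag (X'WX)^-1 per feature
    sigma2: pd.Series  # residual variance
    df_residual: int
    amean: pd.Series  # mean log-expression per feature


def fit_weighted_lm(
    y: pd.DataFrame,
    design: np.ndarray,
    weights: pd.DataFrame | None = None,
    coef_names: list[str] | None = None,
) -> LMFit:
    """Weighted least squares for every feature against a shared design.

    Solves the per-feature normal equations in a single batched pass; the
    residual variance is the weighted RSS over the residual degrees of
    freedom.  Rank-deficient designs are rejected with the offending
    columns named.
    """
    Y = y.to_numpy(dtype=float)
    X = np.asarray(design, dtype=float)
    n_feat, n_samp = Y.shape
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name dependent columns by greedy QR check
        bad = []
        cols: list[int] = []
        for j in range(p):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(j)
            else:
                bad.append(coef_names[j] if coef_names else f"col{j}")
        raise ValueError(f"design is rank deficient; dependent columns: {bad}")
    df = n_samp - p
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")

    if weights is None:
        W = np.ones_like(Y)
    else:
        W = weights.to_numpy(dtype=float)
        if (W <= 0).any():
            raise ValueError("weights must be strictly positive")

    # batched normal equations: for each feature g, (X' W_g X) b = X' W_g y
    XtWX = np.einsum("gn,np,nq->gpq", W, X, X)
    XtWy = np.einsum("gn,np,gn->gp", W, X, Y)
    XtWX_inv = np.linalg.inv(XtWX)
    beta = np.einsum("gpq,gq->gp", XtWX_inv, XtWy)
    resid = Y - beta @ X.T
    sigma2 = np.einsum("gn,gn->g", W * resid, resid) / df
    stdev_unscaled = np.sqrt(np.einsum("gpp->gp", XtWX_inv))

    names = coef_names or [f"x{j}" for j in range(p)]
    return LMFit(
        coefficients=pd.DataFrame(beta, index=y.index, columns=names),
        stdev_unscaled=pd.DataFrame(stdev_unscaled, index=y.index, columns=names),
        sigma2=pd.Series(sigma2, index=y.index),
        df_residual=df,
        amean=pd.Series(Y.mean(axis=1), index=y.index),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) on log variances.

    Matches the mean and excess variance of ``log(s^2)`` against the
    digamma/trigamma moments of the log scaled-F distribution; returns
    ``(inf, exp(mean))`` when the observed spread is at or below the
    sampling spread (no evidence of between-feature variance heterogeneity).
    """
    s2 = np.asarray(sigma2, dtype=float)
    if not np.all(np.isfinite(s2)) or (s2 < 0).any():
        raise ValueError("residual variances must be finite and nonnegative")
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2 * half_d0
    s02 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return float(d0), s02


def ebayes_moderate(
    fit: LMFit,
    coef: str,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics for one coefficient of a weighted fit.

    The posterior variance shrinks each feature's residual variance toward
    the prior: ``s2_post = (d0*s0^2 + df*s^2) / (d0 + df)``; the moderated t
    is the coefficient over its shrunk standard error with ``d0 + df``
    degrees of freedom.  ``prior=(0, .)`` recovers the ordinary t-test;
    ``prior=(inf, s0^2)`` forces every posterior variance to ``s0^2``.
    """
    if len(fit.sigma2) < 10 and prior is None:
        raise ValueError("need >= 10 features to estimate the variance prior")
    d = fit.df_residual
    s2 = fit.sigma2.to_numpy()
    if prior is None:
        d0, s02 = estimate_variance_prior(s2, d)
    else:
        d0, s02 = prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    beta = fit.coefficients[coef].to_numpy()
    su = fit.stdev_unscaled[coef].to_numpy()
    se = np.sqrt(s2_post) * su
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "effect": beta,
            "t": t,
            "p": p,
            "s2_post": s2_post,
            "df_prior": d0,
            "df_total": df_total,
            "mean_expr": fit.amean.to_numpy(),
        },
        index=fit.coefficients.index,
    )


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.isnan(p).any():
        raise ValueError("NaN p-values rejected")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Named contrast plus nuisance structure for :func:`run_differential`.

    ``contrast`` is ``"MO3-BL"`` (paired treatment effect; subject fixed
    effects added when ``paired``) or ``"GR-NR"`` (baseline responder vs
    non-responder difference; restricted to BL samples).  ``covariates``
    names additional metadata columns entered as nuisance terms (categorical
    columns are dummy-coded).
    """

    contrast: str = "MO3-BL"
    paired: bool = True
    covariates: list[str] = field(default_factory=list)
    visit_col: str = "visit"
    response_col: str = "response"
    subject_col: str = "subject"


def build_design(meta: pd.DataFrame, spec: DesignSpec) -> tuple[np.ndarray, list[str], str]:
    """Design matrix, coefficient names and the name of the contrast column."""
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if spec.contrast == "MO3-BL":
        cols.append((meta[spec.visit_col] == "MO3").to_numpy(dtype=float))
        names.append("MO3-BL")
        if spec.paired:
            subs = pd.unique(meta[spec.subject_col])
            for s in subs[1:]:
                cols.append((meta[spec.subject_col] == s).to_numpy(dtype=float))
                names.append(f"subject[{s}]")
    elif spec.contrast == "GR-NR":
        resp = meta[spec.response_col].astype(str)
        cols.append(resp.isin(["good", "GR"]).to_numpy(dtype=float))
        names.append("GR-NR")
    else:
        raise ValueError(f"unknown contrast {spec.contrast!r}")
    for cov in spec.covariates:
        v = meta[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(dtype=float))
            names.append(cov)
        else:
            for level in sorted(pd.unique(v.astype(str)))[1:]:
                cols.append((v.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    return np.column_stack(cols), names, names[1]


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 3
) -> pd.DataFrame:
    """Drop features without ``min_count`` reads in ``min_samples`` samples."""
    keep = (counts.to_numpy() >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def run_differential(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    is_counts: bool = True,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Run the full chain for one contrast and return the effect table.

    Counts route through log-CPM and mean-variance precision weights;
    intensity matrices are modelled on their (log) scale with unit weights.
    The returned frame has one row per feature: ``effect`` (log2 scale),
    moderated ``t``, raw ``p``, BH-FDR ``q``, ``mean_expr`` and the degrees
    of freedom used.
    """
    meta = meta.loc[matrix.columns]
    if spec.contrast == "GR-NR":
        keep = meta[spec.visit_col] == "BL" if spec.visit_col in meta else slice(None)
        meta = meta.loc[keep] if not isinstance(keep, slice) else meta
        matrix = matrix[meta.index]
    X, names, contrast_col = build_design(meta, spec)
    # require both contrast levels populated
    contrast_vec = X[:, names.index(contrast_col)]
    if min((contrast_vec == 1).sum(), (contrast_vec == 0).sum()) < 2:
        raise ValueError("contrast needs >= 2 samples per level")

    if is_counts:
        matrix = filter_low_counts(matrix)
        lib = matrix.sum(axis=0).to_numpy()
        y = log_cpm(matrix)
        w = voom_weights(y, X, lib_size=lib)
    else:
        y = matrix
        w = None
    fit = fit_weighted_lm(y, X, w, coef_names=names)
    table = ebayes_moderate(fit, contrast_col, prior=prior)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["df_residual"] = fit.df_residual
    return table
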