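"""Complete-blood-count ratios, paired ratio changes and logistic response models.

Whole-blood innate/adaptive balance is summarised by three natural-log cell
count ratios — neutrophil-to-lymphocyte (NLR), neutrophil-to-WBC (NWR) and
lymphocyte-to-WBC (LWR), with log NWR - log LWR = log NLR by construction.
The module estimates the paired month-3 : baseline change of a ratio as a
geometric-mean percentage with a t-interval on the log scale, and fits
logistic models of good-or-moderate EULAR response on the baseline
log-ratios, unadjusted or adjusted for the a-priori clinical covariates,
reporting odds ratios with Wald intervals.  A generic Pearson chi-square
test covers R x C genotype-by-response tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class SeparationError(RuntimeError):
    """Raised when maximum-likelihood logistic estimates do not exist."""


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def cbc_log_ratios(
    neutrophils, lymphocytes, wbc
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural-log NLR, NWR, LWR from positive cell counts (10^9/L)."""
    n = np.asarray(neutrophils, dtype=float)
    l = np.asarray(lymphocytes, dtype=float)
    w = np.asarray(wbc, dtype=float)
    if (n <= 0).any() or (l <= 0).any() or (w <= 0).any():
        raise ValueError("cell counts must be strictly positive")
    return np.log(n / l), np.log(n / w), np.log(l / w)


def cbc_ratio_table(cbc: pd.DataFrame) -> pd.DataFrame:
    """Attach log_nlr / log_nwr / log_lwr columns to a CBC table."""
    nlr, nwr, lwr = cbc_log_ratios(
        cbc["neutrophils"], cbc["lymphocytes"], cbc["wbc"]
    )
    out = cbc.copy()
    out["log_nlr"], out["log_nwr"], out["log_lwr"] = nlr, nwr, lwr
    return out


# ---------------------------------------------------------------------------
# paired BL -> MO3 ratio change
# ---------------------------------------------------------------------------

def paired_ratio_change(
    bl_values: pd.Series, mo3_values: pd.Series, conf_level: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """Geometric-mean MO3:BL change as percent of baseline, with t-CI and p.

    ``bl_values`` and ``mo3_values`` are positive ratios (e.g. neutrophil /
    WBC) indexed by subject.  The estimate is ``exp(mean(log(MO3 / BL)))``
    expressed in percent; the interval is a t-interval on the paired log
    differences, exponentiated; the p-value is a two-sided one-sample t test
    of the log differences against zero.  Unpaired subjects are dropped with
    a warning.
    """
    shared = bl_values.index.intersection(mo3_values.index)
    dropped = (len(bl_values) - len(shared)) + (len(mo3_values) - len(shared))
    if dropped:
        warnings.warn(f"{dropped} unpaired value(s) dropped", stacklevel=2)
    if len(shared) < 3:
        raise ValueError("need >= 3 paired subjects")
    bl = bl_values.loc[shared].to_numpy(dtype=float)
    mo3 = mo3_values.loc[shared].to_numpy(dtype=float)
    if (bl <= 0).any() or (mo3 <= 0).any():
        raise ValueError("ratios must be strictly positive")
    d = np.log(mo3 / bl)
    n = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    est = float(np.exp(mean) * 100.0)
    if sd == 0:
        ci = (est, est)
        p = 1.0 if mean == 0 else 0.0
        return est, ci, p
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + conf_level / 2, n - 1)
    ci = (
        float(np.exp(mean - tcrit * se) * 100.0),
        float(np.exp(mean + tcrit * se) * 100.0),
    )
    p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return est, ci, p


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Logistic model fit: per-term OR, Wald CI and p, plus diagnostics."""

    table: pd.DataFrame  # index term; columns coef, se, or, ci_low, ci_high, p
    n: int
    converged: bool
    llf: float
    n_dropped: int = 0
    terms: list[str] = field(default_factory=list)

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "or"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def logistic_fit(
    design: pd.DataFrame, outcome, add_intercept: bool = True
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald odds-ratio intervals.

    Fits by iteratively reweighted least squares (binomial GLM, logit link);
    Wald standard errors come from the observed information at the optimum.
    Complete or quasi-complete separation — diverging coefficients with the
    likelihood saturating — is detected and raised as
    :class:`SeparationError` rather than reported as a spuriously precise
    fit.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary (0/1)")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; model is not identifiable")
    X = design.copy()
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
        except Exception as err:  # statsmodels raises on hard separation
            raise SeparationError(str(err)) from err
    mu = res.fittedvalues
    saturated = np.all((mu[y == 1] > 1 - 1e-6)) and np.all(mu[y == 0] < 1e-6)
    if saturated or np.abs(res.params.to_numpy()).max() > 30:
        raise SeparationError(
            "complete or quasi-complete separation: coefficients diverge "
            "and the likelihood saturates"
        )
    coefs = res.params
    ses = res.bse
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "or": np.exp(coefs),
            "ci_low": np.exp(coefs - z * ses),
            "ci_high": np.exp(coefs + z * ses),
            "p": 2 * stats.norm.sf(np.abs(coefs / ses)),
        }
    )
    return LogisticFit(
        table=table,
        n=int(y.size),
        converged=bool(res.converged),
        llf=float(res.llf),
        terms=list(X.columns),
    )


#: the seven a-priori covariates of the adjusted response model, mapped to
#: the scaling conventions used for reporting (age and disease duration per
#: 10 years; mHAQ per unit; prior biologics per additional agent)
ADJUSTED_COVARIATES = (
    "drug_tnfi",
    "age10",
    "smoking",
    "duration10",
    "mhaq",
    "mtx",
    "n_prior_biologics",
)


def response_model(
    cbc: pd.DataFrame,
    meta: pd.DataFrame,
    ratio: str = "nlr",
    adjusted: bool = False,
    response_col: str = "response",
    covariates: tuple[str, ...] = ADJUSTED_COVARIATES,
) -> tuple[LogisticFit, pd.DataFrame]:
    """Logistic model of good-or-moderate response on a baseline CBC log-ratio.

    ``ratio`` is ``"nlr"``, ``"nwr"`` or ``"lwr"``; the covariate enters as
    the natural-log ratio, so the OR is per 1 log-unit increase.  The
    adjusted model adds the a-priori covariates (columns of ``meta``,
    already on their reporting scales).  Rows with missing covariates are
    listwise-deleted with the count reported on the fit.  Returns the fit
    and a forest-plot export frame (term, OR, CI bounds, p).
    """
    if ratio not in ("nlr", "nwr", "lwr"):
        raise ValueError("ratio must be one of 'nlr', 'nwr', 'lwr'")
    rt = cbc_ratio_table(cbc)
    col = f"log_{ratio}"
    resp = meta.loc[rt.index, response_col].astype(str)
    y = resp.isin(["good", "moderate"]).astype(float)
    if y.min() == y.max():
        raise SeparationError("outcome is constant; model is not identifiable")
    design = pd.DataFrame({col: rt[col]})
    if adjusted:
        for c in covariates:
            design[c] = pd.to_numeric(meta.loc[rt.index, c], errors="coerce")
    keep = design.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    fit = logistic_fit(design.loc[keep], y.loc[keep].to_numpy())
    fit.n_dropped = n_dropped
    forest = (
        fit.table.drop(index="const", errors="ignore")
        .reset_index()
        .rename(columns={"index": "term"})[
            ["term", "or", "ci_low", "ci_high", "p"]
        ]
    )
    return fit, forest


# ---------------------------------------------------------------------------
# genotype association
# ---------------------------------------------------------------------------

def genotype_association(
    tables: np.ndarray | list, pool: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of an R x C genotype-by-response table.

    ``tables`` is a single table or a list of same-shape tables; with
    ``pool=True`` the tables are summed entry-wise before testing (as when
    combining cohorts).  No continuity correction is applied (the table may
    exceed 2 x 2).  Zero row/column margins are rejected.
    """
    arr = np.asarray(tables, dtype=float)
    if arr.ndim == 3:
        if not pool:
            raise ValueError("got multiple tables; set pool=True to combine them")
        arr = arr.sum(axis=0)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("expected an R x C table with R, C >= 2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table entries must be nonnegative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)
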