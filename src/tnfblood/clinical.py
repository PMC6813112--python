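"""Clinical scoring, response classification and cohort descriptive statistics.

Implements the DAS28-CRP composite disease-activity score, the EULAR
good/moderate/none response matrix applied to baseline and follow-up scores,
the drug-level exclusion filter for non-responders, and Table-1 style
descriptive summaries comparing good responders (GR) with non-responders
(NR): mean (SD) with two-sample Wilcoxon tests for continuous attributes and
N (%) with Yates-corrected chi-square tests for categorical attributes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# DAS28-CRP and EULAR response
# ---------------------------------------------------------------------------

def das28_crp(tjc28: float, sjc28: float, crp_mg_per_l: float, gh: float) -> float:
    """28-joint disease activity score using C-reactive protein.

    ``0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.36*ln(CRP+1) + 0.014*GH + 0.96``
    with TJC28/SJC28 tender and swollen joint counts in [0, 28], CRP in mg/L
    and GH the 0-100 patient global assessment.
    """
    if not 0 <= tjc28 <= 28 or not 0 <= sjc28 <= 28:
        raise ValueError("joint counts must be in [0, 28]")
    if crp_mg_per_l < 0:
        raise ValueError("CRP must be nonnegative")
    if not 0 <= gh <= 100:
        raise ValueError("patient global assessment must be in [0, 100]")
    return (
        0.56 * math.sqrt(tjc28)
        + 0.28 * math.sqrt(sjc28)
        + 0.36 * math.log(crp_mg_per_l + 1.0)
        + 0.014 * gh
        + 0.96
    )


@dataclass(frozen=True)
class EULARLabel:
    """EULAR response category with the scores that determined it."""

    value: str  # good | moderate | none
    das_bl: float
    das_fu: float

    @property
    def improvement(self) -> float:
        return self.das_bl - self.das_fu


def eular_classify(das_bl: float, das_fu: float) -> EULARLabel:
    """Classify response from baseline and follow-up DAS28 scores.

    The standard EULAR matrix: *good* requires follow-up activity <= 3.2 with
    improvement > 1.2; *none* is improvement <= 0.6, or improvement <= 1.2
    with follow-up activity > 5.1; everything else is *moderate*.
    """
    for name, v in (("das_bl", das_bl), ("das_fu", das_fu)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and nonnegative")
    improvement = das_bl - das_fu
    if das_fu <= 3.2 and improvement > 1.2:
        value = "good"
    elif improvement <= 0.6 or (improvement <= 1.2 and das_fu > 5.1):
        value = "none"
    else:
        value = "moderate"
    return EULARLabel(value=value, das_bl=das_bl, das_fu=das_fu)


# ---------------------------------------------------------------------------
# Two-group tests
# ---------------------------------------------------------------------------

def chi_square_yates(table: np.ndarray | list) -> tuple[float, float]:
    """Yates continuity-corrected chi-square test on a 2x2 table.

    Returns ``(statistic, p)`` with p from the upper tail of chi-square with
    one degree of freedom.  Degenerate tables (a zero row or column margin)
    are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(stat), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon (Mann-Whitney) rank-sum test, two-sided.

    Exact enumeration when the pooled sample has at most 20 observations and
    no ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Cohort filter and Table-1 summary
# ---------------------------------------------------------------------------

def cohort_filter(
    meta: pd.DataFrame,
    drug_level_col: str = "drug_level_mo3",
    response_col: str = "response",
    threshold: float = 800.0,
    missing: str = "keep",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude non-responders with sub-therapeutic MO3 drug levels.

    Non-responders whose MO3 adalimumab/infliximab plasma level is strictly
    below ``threshold`` (ng/mL) are removed, since apparent non-response with
    low drug exposure may reflect anti-drug antibodies rather than biology.
    Responders are never filtered.  ``missing`` controls non-responders with
    no drug level: ``"keep"`` retains them with a warning, ``"drop"``
    excludes them.  Returns the filtered metadata and a log of decisions.
    """
    if missing not in ("keep", "drop"):
        raise ValueError("missing must be 'keep' or 'drop'")
    is_nr = meta[response_col].astype(str).str.lower().isin(["none", "nr"])
    level = pd.to_numeric(meta[drug_level_col], errors="coerce")
    below = is_nr & level.notna() & (level < threshold)
    unknown = is_nr & level.isna()
    if unknown.any() and missing == "keep":
        warnings.warn(
            f"{int(unknown.sum())} non-responder(s) have no MO3 drug level; kept",
            stacklevel=2,
        )
    drop = below | (unknown if missing == "drop" else False)
    log = pd.DataFrame(
        {
            "sample": meta.index,
            "is_nonresponder": is_nr.values,
            "drug_level_mo3": level.values,
            "excluded": drop.values,
        }
    )
    return meta.loc[~drop].copy(), log


@dataclass
class Table1Row:
    attribute: str
    kind: str
    group_summaries: dict[str, str]
    p_value: float | None
    note: str = ""


def table1_summary(
    meta: pd.DataFrame,
    attribute_types: dict[str, str],
    group_col: str = "response",
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Descriptive GR-vs-NR comparison table with per-attribute p-values.

    ``attribute_types`` maps column name to ``"continuous"`` or
    ``"categorical"``.  Continuous attributes are summarised as mean (SD)
    and tested with the two-sample Wilcoxon rank-sum test; binary
    categoricals as N (%) with the Yates chi-square test.  Categorical
    attributes with a single observed level are reported with an undefined
    p-value and flagged.
    """
    if groups is None:
        groups = tuple(pd.unique(meta[group_col]))[:2]
    if len(groups) != 2:
        raise ValueError("need exactly two comparison groups")
    g1 = meta[meta[group_col] == groups[0]]
    g2 = meta[meta[group_col] == groups[1]]

    rows: list[Table1Row] = []
    for attr, kind in attribute_types.items():
        if kind == "continuous":
            x = pd.to_numeric(g1[attr], errors="coerce").dropna()
            y = pd.to_numeric(g2[attr], errors="coerce").dropna()
            _, p = wilcoxon_rank_sum(x, y)
            summ = {
                g: f"{v.mean():.3g} ({v.std(ddof=1):.3g})"
                for g, v in zip(groups, (x, y))
            }
            rows.append(Table1Row(attr, kind, summ, p))
        elif kind == "categorical":
            levels = sorted(pd.unique(meta[attr].dropna().astype(str)))
            if len(levels) < 2:
                rows.append(
                    Table1Row(
                        attr,
                        kind,
                        {g: "" for g in groups},
                        None,
                        note="single observed level; p undefined",
                    )
                )
                continue
            for level in levels:
                a = int((g1[attr].astype(str) == level).sum())
                b = int((g2[attr].astype(str) == level).sum())
                table = [[a, len(g1) - a], [b, len(g2) - b]]
                try:
                    _, p = chi_square_yates(table)
                    note = ""
                except ValueError as err:
                    p, note = None, str(err)
                summ = {
                    g: f"{n} ({100 * n / len(gr):.0f})"
                    for g, n, gr in zip(groups, (a, b), (g1, g2))
                }
                rows.append(Table1Row(f"{attr}={level}", kind, summ, p, note))
        else:
            raise ValueError(f"unknown attribute type {kind!r} for {attr!r}")

    out = pd.DataFrame(
        {
            "attribute": [r.attribute for r in rows],
            "type": [r.kind for r in rows],
            groups[0]: [r.group_summaries[groups[0]] for r in rows],
            groups[1]: [r.group_summaries[groups[1]] for r in rows],
            "p": [r.p_value for r in rows],
            "note": [r.note for r in rows],
        }
    )
    return out


def table1_to_markdown(table: pd.DataFrame) -> str:
    """Render a :func:`table1_summary` result as a Markdown table."""
    cols = list(table.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in table.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                cells.append("" if pd.isna(v) else f"{v:.2g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
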