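"""Cross-cohort concordance of differential-expression effect profiles.

Agreement between two cohorts' per-feature contrast effects is measured by
Spearman rank correlation; its significance comes from a permutation null
that re-estimates both effect vectors after permuting the contrast labels
independently within each dataset (sign-flipping BL/MO3 within subject for
paired contrasts).  The comparison can be restricted to the most variable
features, ranked by baseline log-CPM variance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._effects import dataset_rng, prepare_contrast
from .diffexpr import DesignSpec


def spearman_rho(x, y) -> float:
    """Spearman correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class ConcordanceResult:
    """Observed cross-dataset rank correlation with its permutation p."""

    rho: float
    n_features: int
    p: float
    n_permutations: int
    seed: int
    subset: str = "all features"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def permutation_concordance(
    matrix_a: pd.DataFrame,
    meta_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    meta_b: pd.DataFrame,
    spec: DesignSpec,
    n_perm: int = 1000,
    seed: int = 0,
    features: list[str] | None = None,
    is_counts: bool = True,
    subset_label: str | None = None,
) -> ConcordanceResult:
    """Permutation test of cross-dataset effect concordance.

    The observed statistic is the Spearman correlation of the two datasets'
    contrast-effect vectors on shared features.  The null permutes contrast
    labels independently within each dataset (within-subject BL/MO3
    sign-flips for paired contrasts) and recomputes both effect vectors;
    the two-sided p-value is ``(1 + #{|rho_null| >= |rho_obs|}) /
    (n_perm + 1)``.  Each dataset's permutation stream is keyed by the seed
    and its own sample units, so swapping the roles of the two datasets
    leaves the p-value unchanged.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    pa = prepare_contrast(matrix_a, meta_a, spec, is_counts=is_counts)
    pb = prepare_contrast(matrix_b, meta_b, spec, is_counts=is_counts)
    shared = pa.features.intersection(pb.features)
    if features is not None:
        shared = shared.intersection(pd.Index(features))
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared features (< 50)")
    ia = pa.features.get_indexer(shared)
    ib = pb.features.get_indexer(shared)

    def rho_of(ea: np.ndarray, eb: np.ndarray) -> float:
        return spearman_rho(ea[ia], eb[ib])

    obs = rho_of(pa.effects(), pb.effects())
    rng_a = dataset_rng(seed, pa)
    rng_b = dataset_rng(seed, pb)
    exceed = 0
    for _ in range(n_perm):
        ra = pa.effects(pa.null_draw(rng_a))
        rb = pb.effects(pb.null_draw(rng_b))
        if abs(rho_of(ra, rb)) >= abs(obs):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return ConcordanceResult(
        rho=obs,
        n_features=len(shared),
        p=p,
        n_permutations=n_perm,
        seed=seed,
        subset=subset_label or ("all features" if features is None else "custom subset"),
    )


def top_variable_subset(
    logcpm_baseline: pd.DataFrame, fraction: float
) -> list[str]:
    """Features with the highest baseline log-CPM variance (pooled samples).

    Features are ranked by variance across all baseline samples; ties break
    by feature identifier for determinism.  ``fraction=1.0`` returns all
    features; the subset size is ``round(fraction * n)``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    var = logcpm_baseline.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    k = int(round(fraction * len(order)))
    if k < 1:
        raise ValueError("subset is empty")
    return order[:k]
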