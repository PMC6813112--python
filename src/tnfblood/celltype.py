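"""Cell-type-specific analysis of contrast effects.

From a cell-type reference, each gene gets a specificity score per cell
type: the log2 fold difference between that cell type's reference
expression and the mean of all other cell types.  Genes clearing a score
threshold in exactly one cell type form disjoint marker sets.  Contrast
effects are then summarised per set (mean effect with a label-permutation
p-value, combined across cohorts by averaging) and rolled up to the
innate/adaptive compartment level, testing whether innate sets (neutrophils,
monocytes) move together and opposite to adaptive sets (B, T, NK).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._effects import dataset_rng, prepare_contrast
from .concordance import spearman_rho
from .diffexpr import DesignSpec
from .reference import CellTypeReference


def specificity_scores(
    reference: CellTypeReference, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Gene x cell-type log2 specificity: type vs mean of the other types.

    ``score(g, c) = log2((ref[c, g] + eps) / (mean_{c' != c} ref[c', g] + eps))``.
    A gene expressed equally everywhere scores 0 for every cell type; the
    pseudocount bounds the ratio for dropout genes.
    """
    prof = reference.profiles
    if prof.shape[0] < 2:
        raise ValueError("need at least 2 cell types")
    vals = prof.to_numpy(dtype=float)
    total = vals.sum(axis=0)
    scores = {}
    for i, ct in enumerate(prof.index):
        others = (total - vals[i]) / (vals.shape[0] - 1)
        scores[ct] = np.log2((vals[i] + pseudocount) / (others + pseudocount))
    return pd.DataFrame(scores, index=prof.columns)


def build_marker_sets(
    scores: pd.DataFrame, threshold: float = 2.0, min_size: int = 10
) -> dict[str, list[str]]:
    """Disjoint marker gene sets: argmax cell type with score >= threshold.

    Sets smaller than ``min_size`` are excluded with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    best = scores.idxmax(axis=1)
    best_score = scores.max(axis=1)
    sets: dict[str, list[str]] = {ct: [] for ct in scores.columns}
    for gene in scores.index[best_score >= threshold]:
        sets[best[gene]].append(gene)
    out = {}
    for ct, genes in sets.items():
        if len(genes) < min_size:
            warnings.warn(
                f"marker set for {ct!r} has {len(genes)} genes (< {min_size}); excluded",
                stacklevel=2,
            )
        else:
            out[ct] = genes
    return out


def effect_specificity_correlation(
    effect_table: pd.DataFrame,
    scores: pd.DataFrame,
    cell_type: str,
    min_genes: int = 100,
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation of per-gene effects with one cell type's scores.

    Returns the correlation and the paired (effect, score) frame for 2D
    density plotting.  A negative correlation for neutrophils under a
    neutrophil-depleting treatment is the expected signature.
    """
    shared = effect_table.index.intersection(scores.index)
    if len(shared) < min_genes:
        raise ValueError(f"only {len(shared)} shared genes (< {min_genes})")
    eff = effect_table.loc[shared, "effect"]
    sc = scores.loc[shared, cell_type]
    rho = spearman_rho(eff.to_numpy(), sc.to_numpy())
    return rho, pd.DataFrame({"effect": eff, "specificity": sc})


@dataclass
class CellTypeSetResult:
    """Mean contrast effect of one cell type's marker set, with permutation p."""

    cell_type: str
    compartment: str
    mean_effect: float
    p: float
    set_size: int
    n_permutations: int

    def to_dict(self) -> dict:
        return asdict(self)


def set_effect_with_permutation(
    datasets: list[tuple[pd.DataFrame, pd.DataFrame]],
    spec: DesignSpec,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    is_counts: bool = True,
    cell_type: str = "",
    compartment: str = "",
    min_size: int = 10,
) -> CellTypeSetResult:
    """Permutation test of the mean contrast effect over a gene set.

    The statistic is the mean effect of the set's genes, averaged across
    the supplied cohorts; the null permutes contrast labels within each
    cohort (sign-flips within subject for paired contrasts) and recombines
    by the same averaging.  Two-sided p with the add-one estimator.
    """
    if len(gene_set) < min_size:
        raise ValueError(f"gene set has {len(gene_set)} genes (< {min_size})")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    prepared = [
        prepare_contrast(m, meta, spec, is_counts=is_counts) for m, meta in datasets
    ]
    idxs = []
    for p_ in prepared:
        idx = p_.features.get_indexer(pd.Index(gene_set))
        idx = idx[idx >= 0]
        if idx.size == 0:
            raise ValueError("gene set absent from a dataset after filtering")
        idxs.append(idx)

    def stat(effects: list[np.ndarray]) -> float:
        return float(np.mean([e[i].mean() for e, i in zip(effects, idxs)]))

    obs = stat([p_.effects() for p_ in prepared])
    rngs = [dataset_rng(seed, p_) for p_ in prepared]
    exceed = 0
    for _ in range(n_perm):
        null = stat(
            [p_.effects(p_.null_draw(r)) for p_, r in zip(prepared, rngs)]
        )
        if abs(null) >= abs(obs):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    n_genes = int(min(len(i) for i in idxs))
    return CellTypeSetResult(
        cell_type=cell_type,
        compartment=compartment,
        mean_effect=obs,
        p=p,
        set_size=n_genes,
        n_permutations=n_perm,
    )


def innate_adaptive_summary(results: list[CellTypeSetResult]) -> dict:
    """Compartment-level roll-up of set effects with a sign-concordance flag.

    ``concordant`` is true when every innate set shares one sign and every
    adaptive set the opposite sign; ``direction`` reports which compartment
    is up ("innate-up" / "adaptive-up") when concordant.
    """
    by_comp: dict[str, list[float]] = {"innate": [], "adaptive": []}
    for r in results:
        if r.compartment not in by_comp:
            raise ValueError(f"unknown compartment {r.compartment!r}")
        by_comp[r.compartment].append(r.mean_effect)
    for comp, effs in by_comp.items():
        if not effs:
            raise ValueError(f"no results for the {comp} compartment")
    innate, adaptive = by_comp["innate"], by_comp["adaptive"]
    innate_sign = {np.sign(e) for e in innate}
    adaptive_sign = {np.sign(e) for e in adaptive}
    concordant = (
        len(innate_sign) == 1
        and len(adaptive_sign) == 1
        and innate_sign != adaptive_sign
    )
    direction = None
    if concordant:
        direction = "innate-up" if innate[0] > 0 else "adaptive-up"
    return {
        "innate_mean": float(np.mean(innate)),
        "adaptive_mean": float(np.mean(adaptive)),
        "concordant": bool(concordant),
        "direction": direction,
    }


def export_volcano(results: list[CellTypeSetResult], path: str | Path) -> None:
    """Volcano-style TSV export: mean effect vs -log10 permutation p per set."""
    rows = [
        {
            "cell_type": r.cell_type,
            "compartment": r.compartment,
            "mean_effect": r.mean_effect,
            "neg_log10_p": -np.log10(r.p),
            "set_size": r.set_size,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_results_json(results: list[CellTypeSetResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
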