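"""Configuration-driven orchestration of the full analysis sequence.

Two entry points mirror the study's two questions:

* :func:`run_treatment_analysis` — the month-3 vs baseline treatment
  signature: per-cohort paired differential expression, cross-cohort
  concordance with a permutation null, the neutrophil effect-vs-specificity
  correlation, and the paired CBC neutrophil/WBC ratio change;
* :func:`run_baseline_response_analysis` — baseline differences between
  good responders and non-responders: GR-NR effect tables, all-gene and
  top-variable-subset concordance, per-cell-type marker-set statistics with
  the innate/adaptive roll-up, and CBC log-ratio logistic response models.

All stochastic stages draw named sub-seeds from one master seed; every run
writes a reproducibility manifest (seeds, package version, config, outputs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cbc, celltype, concordance, diffexpr, reference, simulate


def subseed(master: int, index: int) -> int:
    """Named sub-seed derived from the master seed (stable, < 2^31)."""
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Run settings: synthetic-generation parameters, thresholds, seeds, paths."""

    outdir: str = "run_output"
    seed: int = 0
    synthetic: bool = True
    # synthetic generation
    n_genes: int = 600
    marker_fraction: float = 0.5
    n_subjects: dict = field(
        default_factory=lambda: {"C1": [19, 21], "C2": [21, 15]}
    )
    treatment_neutrophil_multiplier: float = 0.87
    response_innate_shift: float = 0.15
    cbc_population_n: int = 2000
    cbc_target_or: float = 1.2
    # analysis thresholds
    n_perm: int = 1000
    marker_threshold: float = 2.0
    min_set_size: int = 10
    variable_fraction: float = 0.1
    fdr_level: float = 0.05
    # user-supplied inputs (used when synthetic is false)
    input_paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        if not cfg.synthetic:
            for key, p in cfg.input_paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"input {key!r} not found: {p}")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _load_or_generate(cfg: RunConfig):
    """Return (reference, {cohort: (counts, meta, cbc_table, truth|None)})."""
    if cfg.synthetic:
        ref = reference.generate_reference(
            cfg.n_genes, cfg.marker_fraction, seed=subseed(cfg.seed, 0)
        )
        cohorts = {}
        for i, (cname, (n_gr, n_nr)) in enumerate(cfg.n_subjects.items()):
            params = simulate.GeneratorParams(
                n_subjects_gr=n_gr,
                n_subjects_nr=n_nr,
                treatment_neutrophil_multiplier=cfg.treatment_neutrophil_multiplier,
                response_innate_shift=cfg.response_innate_shift,
                cohort=cname,
                seed=subseed(cfg.seed, 1 + i),
            )
            cohorts[cname] = simulate.generate_cohort(params, ref)
        return ref, cohorts
    paths = cfg.input_paths
    ref = reference.CellTypeReference.from_tsv(
        paths["reference_profiles"], paths["reference_compartments"]
    )
    cohorts = {}
    for cname in paths["cohorts"]:
        cp = paths["cohorts"][cname]
        counts = pd.read_csv(cp["counts"], sep="\t", index_col=0)
        meta = pd.read_csv(cp["meta"], sep="\t", index_col=0)
        cbc_table = (
            pd.read_csv(cp["cbc"], sep="\t", index_col=0) if "cbc" in cp else None
        )
        cohorts[cname] = (counts, meta, cbc_table, None)
    return ref, cohorts


def _write_manifest(outdir: Path, cfg: RunConfig, stage: str, outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "master_seed": cfg.seed,
        "config": asdict(cfg),
        "outputs": sorted(outputs),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_treatment_analysis(cfg: RunConfig) -> dict:
    """Month-3 vs baseline treatment signature across cohorts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, cohorts = _load_or_generate(cfg)
    spec = diffexpr.DesignSpec(contrast="MO3-BL", paired=True)
    scores = celltype.specificity_scores(ref)

    outputs: list[str] = []
    results: dict = {"cohorts": {}}
    names = list(cohorts)
    for cname in names:
        counts, meta, cbc_table, _ = cohorts[cname]
        table = diffexpr.run_differential(counts, meta, spec, is_counts=True)
        path = outdir / f"effects_mo3_bl_{cname}.tsv"
        table.to_csv(path, sep="\t")
        outputs.append(str(path))
        rho_neut, _ = celltype.effect_specificity_correlation(
            table, scores, "neutrophils"
        )
        res_c = {
            "n_genes_tested": int(len(table)),
            "n_significant": int((table["q"] < cfg.fdr_level).sum()),
            "neutrophil_specificity_rho": rho_neut,
        }
        if cbc_table is not None:
            nwr = cbc_table["neutrophils"] / cbc_table["wbc"]
            bl = nwr[cbc_table["visit"] == "BL"]
            mo3 = nwr[cbc_table["visit"] == "MO3"]
            bl.index = cbc_table.loc[bl.index, "subject"]
            mo3.index = cbc_table.loc[mo3.index, "subject"]
            est, ci, p = cbc.paired_ratio_change(bl, mo3)
            res_c["nwr_mo3_percent_of_bl"] = {"estimate": est, "ci": ci, "p": p}
        results["cohorts"][cname] = res_c

    if len(names) >= 2:
        (c1, m1, _, _), (c2, m2, _, _) = cohorts[names[0]], cohorts[names[1]]
        conc = concordance.permutation_concordance(
            c1, m1, c2, m2, spec, n_perm=cfg.n_perm, seed=subseed(cfg.seed, 10)
        )
        conc.to_json(outdir / "concordance_mo3_bl.json")
        outputs.append(str(outdir / "concordance_mo3_bl.json"))
        results["concordance"] = asdict(conc)

    _write_manifest(outdir, cfg, "treatment", outputs)
    return results


def run_baseline_response_analysis(cfg: RunConfig) -> dict:
    """Baseline GR vs NR differences: expression, cell-type sets, CBC models."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, cohorts = _load_or_generate(cfg)
    for cname, (counts, meta, *_rest) in cohorts.items():
        if "response" not in meta.columns or meta["response"].isna().any():
            raise ValueError(f"cohort {cname}: EULAR response labels are required")
    spec = diffexpr.DesignSpec(contrast="GR-NR", paired=False)
    scores = celltype.specificity_scores(ref)
    marker_sets = celltype.build_marker_sets(
        scores, threshold=cfg.marker_threshold, min_size=cfg.min_set_size
    )

    outputs: list[str] = []
    results: dict = {"cohorts": {}}
    names = list(cohorts)
    for cname in names:
        counts, meta, _, _ = cohorts[cname]
        table = diffexpr.run_differential(counts, meta, spec, is_counts=True)
        path = outdir / f"effects_gr_nr_{cname}.tsv"
        table.to_csv(path, sep="\t")
        outputs.append(str(path))
        results["cohorts"][cname] = {
            "n_genes_tested": int(len(table)),
            "n_significant": int((table["q"] < cfg.fdr_level).sum()),
        }

    if len(names) >= 2:
        (c1, m1, _, _), (c2, m2, _, _) = cohorts[names[0]], cohorts[names[1]]
        conc_all = concordance.permutation_concordance(
            c1, m1, c2, m2, spec, n_perm=cfg.n_perm, seed=subseed(cfg.seed, 20)
        )
        bl_cols = m1.index[m1["visit"] == "BL"]
        bl_logcpm = diffexpr.log_cpm(c1[bl_cols])
        # keep at least 50 features so the concordance test stays defined
        frac = max(cfg.variable_fraction, min(1.0, 50 / len(bl_logcpm)))
        top = concordance.top_variable_subset(bl_logcpm, frac)
        conc_top = concordance.permutation_concordance(
            c1,
            m1,
            c2,
            m2,
            spec,
            n_perm=cfg.n_perm,
            seed=subseed(cfg.seed, 21),
            features=top,
            subset_label=f"top {cfg.variable_fraction:.0%} variable",
        )
        results["concordance_all"] = asdict(conc_all)
        results["concordance_top_variable"] = asdict(conc_top)

        datasets = [(c1, m1), (c2, m2)]
        set_results = []
        for i, (ct, genes) in enumerate(sorted(marker_sets.items())):
            set_results.append(
                celltype.set_effect_with_permutation(
                    datasets,
                    spec,
                    genes,
                    n_perm=cfg.n_perm,
                    seed=subseed(cfg.seed, 30 + i),
                    cell_type=ct,
                    compartment=ref.compartment(ct),
                    min_size=cfg.min_set_size,
                )
            )
        celltype.export_volcano(set_results, outdir / "celltype_volcano.tsv")
        celltype.export_results_json(set_results, outdir / "celltype_sets.json")
        outputs += [str(outdir / "celltype_volcano.tsv"), str(outdir / "celltype_sets.json")]
        results["celltype_sets"] = [r.to_dict() for r in set_results]
        results["innate_adaptive"] = celltype.innate_adaptive_summary(set_results)

    # registry-scale CBC response models on a generated population
    cbc_table, labels, covs, truth = simulate.generate_cbc_population(
        cfg.cbc_population_n, cfg.cbc_target_or, seed=subseed(cfg.seed, 40)
    )
    meta_cbc = covs.copy()
    meta_cbc["response"] = labels
    cbc_results = {}
    for ratio in ("nlr", "nwr", "lwr"):
        fit_u, _ = cbc.response_model(cbc_table, meta_cbc, ratio=ratio, adjusted=False)
        fit_a, forest = cbc.response_model(cbc_table, meta_cbc, ratio=ratio, adjusted=True)
        forest.to_csv(outdir / f"forest_{ratio}.tsv", sep="\t", index=False)
        outputs.append(str(outdir / f"forest_{ratio}.tsv"))
        term = f"log_{ratio}"
        cbc_results[ratio] = {
            "unadjusted_or": fit_u.odds_ratio(term),
            "unadjusted_ci": fit_u.ci(term),
            "adjusted_or": fit_a.odds_ratio(term),
            "adjusted_ci": fit_a.ci(term),
            "n": fit_a.n,
        }
    results["cbc_models"] = cbc_results
    results["cbc_truth_or"] = float(np.exp(truth.nlr_log_or_slope))

    _write_manifest(outdir, cfg, "baseline", outputs)
    return results
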