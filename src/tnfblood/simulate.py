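"""Synthetic cohorts of whole-blood counts, proteins, CBC and clinical metadata.

The generator emulates the structure of a two-visit (baseline BL, month-3
MO3) anti-TNF treatment study in rheumatoid arthritis:

* bulk RNA-seq counts arise as negative-binomial draws around cell-type
  mixture means (per-subject cell fractions times reference profiles);
* treatment multiplies the neutrophil fraction at MO3 by a ratio
  (default 0.87, i.e. the MO3 neutrophil share is 87% of baseline);
* good responders (GR) carry an additive baseline shift of the innate
  (neutrophil + monocyte) fraction relative to non-responders (NR);
* CBC neutrophil/lymphocyte/WBC values derive deterministically from the
  true fractions and a lognormal total count, then receive lognormal jitter,
  so marker-set expression and CBC ratios are correlated by construction;
* DAS28-CRP components are back-solved from target scores so that the
  GR/NR labels are consistent with the EULAR response matrix;
* a separate population generator produces CBC tables with a stated
  neutrophil-to-lymphocyte-ratio odds ratio for logistic-recovery tests.

Every draw flows from a single integer seed; ground truth (fractions,
marker assignment, odds-ratio slope) is recorded for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clinical import das28_crp, eular_classify
from .reference import CellTypeReference

# realistic whole-blood leukocyte composition (fractions of WBC)
DEFAULT_BASELINE_FRACTIONS = {
    "neutrophils": 0.55,
    "monocytes": 0.08,
    "B": 0.07,
    "CD4_T": 0.16,
    "CD8_T": 0.09,
    "NK": 0.05,
}


@dataclass
class GeneratorParams:
    """Tunable parameters of the cohort generator.

    ``treatment_neutrophil_multiplier`` is the MO3:BL ratio of the true
    neutrophil fraction (0.87 means a 13% relative reduction at month 3);
    ``response_innate_shift`` is the additive increase of the GR baseline
    innate (neutrophil+monocyte) fraction before renormalisation.
    """

    n_subjects_gr: int = 20
    n_subjects_nr: int = 20
    baseline_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_FRACTIONS)
    )
    treatment_neutrophil_multiplier: float = 0.87
    response_innate_shift: float = 0.15
    library_size_mean: float = 1.0e6
    library_size_cv: float = 0.3
    nb_dispersion: tuple[float, float] = (0.05, 0.4)
    subject_effect_sd: float = 0.12
    cohort: str = "C1"
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.baseline_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"baseline_fractions must sum to 1 (got {total})")
        if any(v < 0 for v in self.baseline_fractions.values()):
            raise ValueError("baseline_fractions must be nonnegative")
        if not 0 < self.treatment_neutrophil_multiplier < 2:
            raise ValueError("treatment_neutrophil_multiplier must be in (0, 2)")
        if self.n_subjects_gr <= 0 or self.n_subjects_nr <= 0:
            raise ValueError("subject counts must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        lo, hi = self.nb_dispersion
        if not 0 < lo <= hi:
            raise ValueError("nb_dispersion range must be positive and ordered")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators, for recovery tests."""

    fractions_bl: pd.DataFrame | None = None  # subject x cell type
    fractions_mo3: pd.DataFrame | None = None
    gene_assignment: dict[str, str] = field(default_factory=dict)
    nlr_log_or_slope: float | None = None
    covariate_slopes: dict[str, float] = field(default_factory=dict)
    effect_features: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def save(self, path: str | Path) -> None:
        doc = {
            "seed": int(self.seed),
            "nlr_log_or_slope": self.nlr_log_or_slope,
            "covariate_slopes": {k: float(v) for k, v in self.covariate_slopes.items()},
            "gene_assignment": dict(self.gene_assignment),
            "effect_features": {k: float(v) for k, v in self.effect_features.items()},
            "params": self.params,
        }
        for name in ("fractions_bl", "fractions_mo3"):
            df = getattr(self, name)
            if df is not None:
                doc[name] = {
                    "index": list(map(str, df.index)),
                    "columns": list(map(str, df.columns)),
                    "values": df.values.tolist(),
                }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        frames = {}
        for name in ("fractions_bl", "fractions_mo3"):
            if name in doc:
                d = doc.pop(name)
                frames[name] = pd.DataFrame(
                    d["values"], index=d["index"], columns=d["columns"]
                )
        return cls(
            fractions_bl=frames.get("fractions_bl"),
            fractions_mo3=frames.get("fractions_mo3"),
            gene_assignment=dict(doc.get("gene_assignment") or {}),
            nlr_log_or_slope=doc.get("nlr_log_or_slope"),
            covariate_slopes=dict(doc.get("covariate_slopes") or {}),
            effect_features=dict(doc.get("effect_features") or {}),
            params=doc.get("params") or {},
            seed=int(doc.get("seed", 0)),
        )

    def equals(self, other: "SyntheticTruth") -> bool:
        for name in ("fractions_bl", "fractions_mo3"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.allclose(a.values, b.values, atol=1e-9):
                return False
        return (
            self.gene_assignment == other.gene_assignment
            and self.seed == other.seed
            and (self.nlr_log_or_slope is None) == (other.nlr_log_or_slope is None)
            and (
                self.nlr_log_or_slope is None
                or math.isclose(self.nlr_log_or_slope, other.nlr_log_or_slope)
            )
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _subject_fractions(
    base: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    f = base * np.exp(rng.normal(0.0, sd, size=base.size))
    return f / f.sum()


def _apply_innate_shift(
    f: np.ndarray, innate_idx: np.ndarray, shift: float
) -> np.ndarray:
    """Add ``shift`` to the innate fraction (split proportionally), renormalise."""
    out = f.copy()
    innate_sum = out[innate_idx].sum()
    if innate_sum + shift <= 0 or innate_sum + shift >= 1 + shift:
        raise ValueError("response_innate_shift produces non-positive fractions")
    out[innate_idx] *= (innate_sum + shift) / innate_sum
    out = out / out.sum()
    if (out <= 0).any():
        raise ValueError("response_innate_shift produces non-positive fractions")
    return out


def _apply_neutrophil_multiplier(
    f: np.ndarray, neut_idx: int, mult: float
) -> np.ndarray:
    """Scale the neutrophil fraction by ``mult``; other cell types absorb
    the difference proportionally, so the MO3:BL neutrophil-fraction ratio
    equals ``mult`` exactly and the vector stays on the simplex."""
    out = f.copy()
    new_neut = min(f[neut_idx] * mult, 0.999)
    rest = 1.0 - f[neut_idx]
    out[neut_idx] = new_neut
    scale = (1.0 - new_neut) / rest
    for i in range(out.size):
        if i != neut_idx:
            out[i] *= scale
    return out


def _backsolve_das28(target: float, rng: np.random.Generator) -> dict[str, float]:
    """Pick (TJC, SJC, CRP, GH) whose DAS28-CRP is close to ``target``.

    Random Dirichlet split of the variable part across the four terms; joint
    counts are rounded to integers and CRP absorbs the rounding residual.
    """
    resid = max(target - 0.96, 0.0)
    for _ in range(50):
        w = rng.dirichlet([2.0, 1.5, 1.5, 1.0])
        tjc = int(np.clip(round((w[0] * resid / 0.56) ** 2), 0, 28))
        sjc = int(np.clip(round((w[1] * resid / 0.28 / 1.6) ** 2), 0, 28))
        gh = float(np.clip(w[3] * resid / 0.014, 0, 100))
        rest = resid - 0.56 * math.sqrt(tjc) - 0.28 * math.sqrt(sjc) - 0.014 * gh
        crp = math.exp(rest / 0.36) - 1.0
        if 0.0 <= crp <= 300.0:
            return {"tjc28": tjc, "sjc28": sjc, "crp": crp, "gh": gh}
    # fall back: put everything achievable into GH and CRP
    gh = float(np.clip(resid / 0.014, 0, 100))
    crp = max(math.exp((resid - 0.014 * gh) / 0.36) - 1.0, 0.0)
    return {"tjc28": 0, "sjc28": 0, "crp": crp, "gh": gh}


def _das_targets(
    response: str, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (BL, MO3) DAS28 targets consistent with the EULAR label."""
    for _ in range(100):
        if response == "good":
            bl = rng.normal(4.5, 0.78)
            bl = float(np.clip(bl, 3.0, 7.5))
            fu = float(rng.uniform(1.0, min(3.2, bl - 1.25)))
        else:
            bl = rng.normal(5.2, 0.94)
            bl = float(np.clip(bl, 3.5, 8.0))
            fu = float(max(bl - rng.uniform(-0.5, 0.55), 0.5))
        if fu > 0 and eular_classify(bl, fu).value == response.replace("nr", "none"):
            return bl, fu
    raise RuntimeError("could not draw DAS28 targets consistent with label")


# ---------------------------------------------------------------------------
# main cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(
    params: GeneratorParams, reference: CellTypeReference
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one paired BL/MO3 cohort from cell-type mixture means.

    Returns ``(counts, meta, cbc, truth)``: a genes x samples count matrix
    (columns ``<subject>_BL`` / ``<subject>_MO3``), per-sample metadata with
    clinical attributes, a CBC table (10^9 cells/L), and the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    cts = reference.cell_types
    missing = [c for c in cts if c not in params.baseline_fractions]
    if missing:
        raise ValueError(f"baseline_fractions missing cell types: {missing}")
    base = np.array([params.baseline_fractions[c] for c in cts])
    innate_idx = np.array(
        [i for i, c in enumerate(cts) if reference.compartment(c) == "innate"]
    )
    neut_idx = cts.index("neutrophils")

    n_gr, n_nr = params.n_subjects_gr, params.n_subjects_nr
    subjects = [f"{params.cohort}_S{i + 1:02d}" for i in range(n_gr + n_nr)]
    responses = ["good"] * n_gr + ["none"] * n_nr

    frac_bl, frac_mo3 = {}, {}
    for subj, resp in zip(subjects, responses):
        f = _subject_fractions(base, params.subject_effect_sd, rng)
        if resp == "good" and params.response_innate_shift != 0:
            f = _apply_innate_shift(f, innate_idx, params.response_innate_shift)
        frac_bl[subj] = f
        frac_mo3[subj] = _apply_neutrophil_multiplier(
            f, neut_idx, params.treatment_neutrophil_multiplier
        )

    fractions_bl = pd.DataFrame(frac_bl, index=cts).T
    fractions_mo3 = pd.DataFrame(frac_mo3, index=cts).T

    # counts: NB around mixture means scaled to the library size
    profiles = reference.profiles.values  # C x G
    genes = reference.genes
    sigma = math.sqrt(math.log(1 + params.library_size_cv**2))
    alpha = np.exp(
        rng.uniform(
            math.log(params.nb_dispersion[0]),
            math.log(params.nb_dispersion[1]),
            size=len(genes),
        )
    )
    sample_ids, cols, meta_rows, cbc_rows = [], [], [], []
    for subj, resp in zip(subjects, responses):
        das_bl, das_fu = _das_targets(resp, rng)
        drug = rng.choice(["adalimumab", "infliximab"])
        drug_level = float(rng.lognormal(math.log(4000), 0.5))
        age = float(np.clip(rng.normal(55, 12), 22, 85))
        for visit, frac, das in (
            ("BL", fractions_bl.loc[subj].values, das_bl),
            ("MO3", fractions_mo3.loc[subj].values, das_fu),
        ):
            sid = f"{subj}_{visit}"
            lib = params.library_size_mean * math.exp(
                rng.normal(-0.5 * sigma**2, sigma)
            )
            mix = frac @ profiles
            mu = lib * mix / mix.sum()
            r = 1.0 / alpha
            counts = rng.negative_binomial(r, r / (r + mu))
            sample_ids.append(sid)
            cols.append(counts)

            comps = _backsolve_das28(das, rng)
            meta_rows.append(
                {
                    "sample": sid,
                    "subject": subj,
                    "visit": visit,
                    "cohort": params.cohort,
                    "response": resp,
                    "drug": drug,
                    "drug_level_mo3": drug_level,
                    "age": age,
                    "das28_crp": das28_crp(
                        comps["tjc28"], comps["sjc28"], comps["crp"], comps["gh"]
                    ),
                    **comps,
                }
            )

            wbc = float(rng.lognormal(math.log(7.0), 0.25))
            lymph_frac = frac[
                [i for i, c in enumerate(cts) if reference.compartment(c) == "adaptive"]
            ].sum()
            neut = frac[neut_idx] * wbc * math.exp(rng.normal(0, 0.05))
            lymph = lymph_frac * wbc * math.exp(rng.normal(0, 0.05))
            if neut + lymph > 1.0 * wbc:
                scale = 1.0 * wbc / (neut + lymph)
                neut, lymph = neut * scale, lymph * scale
            cbc_rows.append(
                {
                    "sample": sid,
                    "subject": subj,
                    "visit": visit,
                    "neutrophils": neut,
                    "lymphocytes": lymph,
                    "wbc": wbc,
                }
            )

    counts = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=sample_ids
    )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    cbc = pd.DataFrame(cbc_rows).set_index("sample")
    truth = SyntheticTruth(
        fractions_bl=fractions_bl,
        fractions_mo3=fractions_mo3,
        gene_assignment=dict(reference.marker_assignment),
        params={
            "treatment_neutrophil_multiplier": params.treatment_neutrophil_multiplier,
            "response_innate_shift": params.response_innate_shift,
            "cohort": params.cohort,
        },
        seed=params.seed,
    )
    return counts, meta, cbc, truth


# ---------------------------------------------------------------------------
# CBC population with a stated NLR odds ratio
# ---------------------------------------------------------------------------

#: a-priori covariates of the registry response model: (kind, params..., beta)
DEFAULT_CBC_COVARIATES: dict[str, tuple] = {
    "drug_tnfi": ("binary", 0.6, math.log(1.10)),
    "age10": ("normal", 5.6, 1.3, math.log(0.95)),
    "smoking": ("binary", 0.35, math.log(0.90)),
    "duration10": ("normal", 0.9, 0.8, math.log(0.98)),
    "mhaq": ("normal", 0.9, 0.5, math.log(0.85)),
    "mtx": ("binary", 0.6, math.log(1.23)),
    "n_prior_biologics": ("count", 0.8, math.log(0.92)),
}


def generate_cbc_population(
    n: int,
    target_or: float = 1.2,
    covariate_spec: dict[str, tuple] | None = None,
    seed: int = 0,
    response_rate: float = 0.65,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SyntheticTruth]:
    """Registry-scale CBC population with a known NLR odds ratio.

    Good-or-moderate response is drawn from a logistic model whose slope on
    the natural-log neutrophil-to-lymphocyte ratio is ``log(target_or)``,
    plus covariate effects from ``covariate_spec`` (name -> ("binary", p,
    beta) | ("normal", mean, sd, beta) | ("count", lam, beta)).  Returns the
    CBC table, response labels ("good"/"moderate"/"none"), the covariate
    frame, and truth recording the slope.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    if target_or <= 0:
        raise ValueError("target_or must be positive")
    spec = DEFAULT_CBC_COVARIATES if covariate_spec is None else covariate_spec
    rng = np.random.default_rng(seed)

    cov: dict[str, np.ndarray] = {}
    betas: dict[str, float] = {}
    for name, entry in spec.items():
        kind = entry[0]
        if kind == "binary":
            _, p, beta = entry
            if not 0 < p < 1:
                raise ValueError(f"degenerate binary covariate {name!r} (p={p})")
            cov[name] = rng.binomial(1, p, size=n).astype(float)
        elif kind == "normal":
            _, mean, sd, beta = entry
            if sd <= 0:
                raise ValueError(f"degenerate normal covariate {name!r} (sd={sd})")
            cov[name] = rng.normal(mean, sd, size=n)
        elif kind == "count":
            _, lam, beta = entry
            if lam <= 0:
                raise ValueError(f"degenerate count covariate {name!r} (lam={lam})")
            cov[name] = rng.poisson(lam, size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
        betas[name] = float(beta)
    covariates = pd.DataFrame(cov, index=[f"P{i + 1:05d}" for i in range(n)])

    log_nlr = rng.normal(math.log(2.5), 0.55, size=n)
    slope = math.log(target_or)
    eta = slope * log_nlr + sum(
        betas[name] * covariates[name].values for name in covariates
    )
    intercept = math.log(response_rate / (1 - response_rate)) - float(np.mean(eta))
    prob = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    y = rng.binomial(1, prob)
    labels = pd.Series(
        np.where(y == 1, np.where(rng.random(n) < 0.5, "good", "moderate"), "none"),
        index=covariates.index,
        name="response",
    )

    lymph = rng.lognormal(math.log(2.0), 0.2, size=n)
    neut = lymph * np.exp(log_nlr)
    wbc = (neut + lymph) / 0.92 * np.exp(rng.normal(0, 0.03, size=n))
    wbc = np.maximum(wbc, (neut + lymph) / 1.0)
    cbc = pd.DataFrame(
        {"neutrophils": neut, "lymphocytes": lymph, "wbc": wbc},
        index=covariates.index,
    )
    truth = SyntheticTruth(
        nlr_log_or_slope=slope,
        covariate_slopes=betas,
        params={"n": n, "target_or": target_or, "response_rate": response_rate},
        seed=seed,
    )
    return cbc, labels, covariates, truth


# ---------------------------------------------------------------------------
# plasma protein intensities
# ---------------------------------------------------------------------------

@dataclass
class ProteinParams:
    """Two-cohort plasma proteomics generator settings (log2 intensity scale)."""

    n_features: int = 170
    n_subjects: tuple[int, int] = (20, 18)
    n_effect_features: int = 15
    effect_log2_sd: float = 0.6
    subject_sd: float = 0.5
    noise_sd: float = 0.3
    base_mean: float = 20.0
    base_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 140 <= self.n_features <= 200:
            raise ValueError("n_features should emulate a shotgun panel (140-200)")
        if self.n_effect_features < 0 or self.n_effect_features > self.n_features:
            raise ValueError("n_effect_features out of range")


def generate_protein_matrix(
    params: ProteinParams, seed: int = 0
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], SyntheticTruth]:
    """Paired BL/MO3 lognormal protein intensities for two cohorts.

    A designated subset of features carries an MO3-BL shift shared across
    both cohorts (zero-effect runs set ``n_effect_features=0``).  Intensities
    are returned on the log2 scale, features x samples, one matrix and one
    metadata frame per cohort.
    """
    rng = np.random.default_rng(seed)
    feats = [f"PROT{i:04d}" for i in range(params.n_features)]
    base = rng.normal(params.base_mean, params.base_sd, size=params.n_features)
    delta = np.zeros(params.n_features)
    if params.n_effect_features:
        idx = rng.choice(params.n_features, params.n_effect_features, replace=False)
        delta[idx] = rng.normal(0.0, params.effect_log2_sd, size=idx.size)

    matrices, metas = {}, {}
    for c, (cname, n_sub) in enumerate(zip(("C1", "C2"), params.n_subjects)):
        cols, ids, rows = [], [], []
        for s in range(n_sub):
            subj = f"{cname}_P{s + 1:02d}"
            b = base + rng.normal(0.0, params.subject_sd, size=params.n_features)
            for visit in ("BL", "MO3"):
                x = b + (delta if visit == "MO3" else 0.0)
                x = x + rng.normal(0.0, params.noise_sd, size=params.n_features)
                ids.append(f"{subj}_{visit}")
                cols.append(x)
                rows.append(
                    {"sample": ids[-1], "subject": subj, "visit": visit, "cohort": cname}
                )
        matrices[cname] = pd.DataFrame(
            np.column_stack(cols), index=feats, columns=ids
        )
        metas[cname] = pd.DataFrame(rows).set_index("sample")

    truth = SyntheticTruth(
        effect_features={f: float(d) for f, d in zip(feats, delta) if d != 0.0},
        params={"n_features": params.n_features},
        seed=seed,
    )
    return matrices, metas, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(
    outdir: str | Path,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    cbc: pd.DataFrame,
    truth: SyntheticTruth,
    prefix: str = "cohort",
) -> dict[str, Path]:
    """Write a generated cohort as TSV (+ YAML truth) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}_counts.tsv",
        "meta": outdir / f"{prefix}_meta.tsv",
        "cbc": outdir / f"{prefix}_cbc.tsv",
        "truth": outdir / f"{prefix}_truth.yaml",
    }
    counts.to_csv(paths["counts"], sep="\t")
    meta.to_csv(paths["meta"], sep="\t")
    cbc.to_csv(paths["cbc"], sep="\t")
    truth.save(paths["truth"])
    return paths
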