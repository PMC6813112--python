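# tnfblood

Analysis of anti-TNF treatment and response in rheumatoid arthritis (RA)
whole blood, built as a tested pipeline over synthetic (or user-supplied)
data.

## The scientific problem

Roughly a third of RA patients do not respond to TNF-inhibitor therapy, and
no baseline blood marker reliably predicts who will. Two questions drive
the analysis here:

1. **What does anti-TNF treatment do to whole blood?** Paired baseline (BL)
   vs month-3 (MO3) profiling should reveal a pharmacodynamic signature —
   in particular a reduction of the neutrophil compartment — that is
   reproducible across independently processed cohorts and visible in both
   gene expression and complete blood counts (CBC).
2. **Does baseline innate/adaptive balance predict response?** Good
   responders (EULAR-GR) may carry relatively more innate cells
   (neutrophils, monocytes) and non-responders (EULAR-NR) more adaptive
   cells (B, CD4 T, CD8 T, NK) at baseline — testable at the marker-set
   level in expression data and as neutrophil-to-lymphocyte ratios (NLR) in
   registry-scale CBC tables.

## The statistical core

* **Precision-weighted differential expression.** Counts are transformed to
  log2-CPM; a lowess trend of sqrt residual SD against average log-count
  yields per-observation weights w = s(µ)⁻⁴; per-gene weighted least
  squares with subject blocking for paired contrasts; residual variances
  are shrunk toward a scaled-F prior fitted by closed-form moments on
  log s² (trigamma inversion), giving moderated t-statistics
  t̃ = β̂ / (s̃ · u) on d₀ + d degrees of freedom; Benjamini–Hochberg
  step-up FDR.
* **Cross-cohort concordance.** Spearman ρ of two cohorts' effect vectors;
  significance by permuting contrast labels independently within each
  cohort (within-subject BL/MO3 sign-flips for paired contrasts) and
  recomputing both vectors; p = (1 + #{|ρ₀| ≥ |ρ|}) / (B + 1).
* **Cell-type analysis.** Specificity score(g, c) =
  log2((ref₍c,g₎ + ε) / (mean of other cell types + ε)); disjoint marker
  sets by argmax with score ≥ 2; set statistic = mean contrast effect over
  the set, averaged across cohorts, with a label-permutation p; compartment
  roll-up tests the innate-up/adaptive-down sign pattern.
* **Clinical scoring.** DAS28-CRP = 0.56√TJC28 + 0.28√SJC28 +
  0.36·ln(CRP+1) + 0.014·GH + 0.96; EULAR good/moderate/none matrix on
  (follow-up score, improvement); Wilcoxon rank-sum and Yates chi-square
  for cohort descriptive tables.
* **CBC models.** ln NLR / ln NWR / ln LWR; paired MO3:BL ratio change as a
  geometric mean with a t-interval on log differences; logistic regression
  (IRLS, Wald intervals) of good-or-moderate response on baseline
  log-ratios, unadjusted and adjusted for seven a-priori clinical
  covariates.

The synthetic generator (`tnfblood.simulate`) draws negative-binomial
counts around cell-type mixture means, applies a treatment multiplier of
0.87 to the neutrophil fraction at MO3, shifts the innate fraction of
responders at baseline, derives CBC values from the same true fractions,
and back-solves DAS28-CRP components so EULAR labels are consistent — all
with recorded ground truth for recovery tests.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_treatment_signature.py
python analysis/03_baseline_response.py
python analysis/04_cohort_table.py
```

`02_treatment_signature.py` prints (seed 1):

```
cross-cohort MO3-BL concordance: rho = 0.360, permutation p = 0.000999 (600 genes, 1000 permutations)
C1: 9/600 genes at q < 0.05; neutrophil specificity rho = -0.491; CBC N/WBC at MO3 = 88.7% of BL [87.0, 90.5], p = 1.2e-14
C2: 3/600 genes at q < 0.05; neutrophil specificity rho = -0.560; CBC N/WBC at MO3 = 86.3% of BL [83.7, 88.9], p = 9.2e-12
```

The two cohorts share only the designed treatment effect, so the positive
rank correlation with a small permutation p is the expected reproducible
signature; the negative effect-vs-neutrophil-specificity correlations say
neutrophil-specific genes drop at month 3; and the paired CBC estimate
recovers the designed 87% neutrophil/WBC ratio inside both intervals.

`03_baseline_response.py` prints (same seed):

```
  B            [adaptive] mean GR-NR effect = -0.130, p = 0.000999
  CD4_T        [adaptive] mean GR-NR effect = -0.121, p = 0.004
  CD8_T        [adaptive] mean GR-NR effect = -0.107, p = 0.002
  NK           [adaptive] mean GR-NR effect = -0.043, p = 0.176
  monocytes    [innate  ] mean GR-NR effect = +0.107, p = 0.004
  neutrophils  [innate  ] mean GR-NR effect = +0.078, p = 0.000999
innate mean = +0.092, adaptive mean = -0.100, concordant = True (innate-up)
CBC NLR: unadjusted OR = 1.52, adjusted OR = 1.55 [1.30, 1.84] (n = 2000)
```

Innate marker sets are up and adaptive sets down in good responders, the
designed pattern. The logistic NLR odds ratio is estimated from a
population generated with a true OR of 1.2 per log-unit; across seeds the
estimator is unbiased (its 95% interval misses the truth in about 5% of
draws — seed 1 above is one of them, as `tnfblood cbc --seed 2` will show).

A `tnfblood` console script exposes the same stages
(`simulate` / `treatment` / `baseline` / `cbc` / `report`) with a YAML
config for running on user-supplied TSV inputs instead of synthetic data.

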