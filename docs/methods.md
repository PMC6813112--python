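# Methods

## Study structure being emulated

Two independently processed cohorts of biologic-naive RA patients starting
adalimumab or infliximab on background methotrexate (C1: 19 EULAR good
responders + 21 non-responders; C2: 21 + 15), each sampled at baseline (BL)
and month 3 (MO3), with whole-blood RNA-seq counts, plasma protein
intensities, complete blood counts (CBC) and clinical metadata; plus a
registry-scale (~2000 patient) CBC population with known EULAR response
used for logistic response models. The synthetic-data module generates
datasets with exactly this structure and records the ground truth so that
every downstream statistic can be checked as a parameter-recovery or
calibration problem.

## Synthetic-data model

**Counts.** Each subject carries a vector of cell-type fractions over
{neutrophils, monocytes, B, CD4 T, CD8 T, NK} drawn by jittering a
whole-blood baseline composition (55 / 8 / 7 / 16 / 9 / 5%) with lognormal
noise of SD 0.12 and renormalising. Gene means are mixtures of cell-type
reference profiles weighted by these fractions, scaled to a lognormal
library size (mean 10⁶, CV 0.3), and counts are negative-binomial with
per-gene dispersion drawn log-uniformly from [0.05, 0.4] — the standard
overdispersion range for bulk RNA-seq and consistent with the assumptions
of precision-weighted linear modelling. The reference itself is synthetic:
half the genes are markers, expressed 20-fold higher in exactly one cell
type, the rest shared; assignments are recorded for recovery tests.

**Treatment effect.** At MO3 the neutrophil fraction is multiplied by 0.87
(the observed MO3:BL neutrophil/WBC ratio of 87%), the other cell types
absorbing the difference proportionally. The multiplier acts on the
fraction directly, so the true MO3:BL fraction ratio equals the parameter
exactly; renormalising the whole vector instead would dilute it to ~0.94
at these compositions and break the correspondence with the measured
ratio.

**Response effect.** Good responders receive an additive baseline shift of
+0.15 to the innate (neutrophil + monocyte) fraction before
renormalisation, i.e. a GR-vs-NR baseline log-NLR gap of ~0.21. The
magnitude is not published; 0.21 sits mid-range of the log-NLR gaps
(~0.2–0.4) reported between EULAR response groups in the RA
neutrophil-to-lymphocyte literature, and makes the innate-up-in-GR
set-level pattern detectable by permutation across two cohorts, matching
the qualitative finding being emulated. A smaller shift (0.05–0.10) leaves
the per-set signal at ~1 standard error and the sign pattern unrecoverable
— informative as a sensitivity observation, but not representative of the
study structure.

**CBC.** WBC is lognormal (median 7·10⁹/L, SD 0.25 on the log scale);
neutrophil and lymphocyte counts are the true fractions times WBC with 5%
lognormal jitter, clipped so neutrophils + lymphocytes never exceed WBC.
Because CBC and expression derive from the same fractions, the correlation
between marker-set expression and CBC ratios exists by construction.

**Clinical scores.** Target DAS28-CRP values are drawn per response class
(GR: BL ~ N(4.5, 0.78), follow-up uniform below 3.2 with improvement
> 1.2; NR: BL ~ N(5.2, 0.94), improvement uniform in (−0.5, 0.55)), then
the four score components are back-solved by a random Dirichlet split with
joint counts rounded and CRP absorbing the residual; draws are rejected
until the realised scores classify to the intended EULAR label, so labels
and scores are always consistent.

**CBC population.** log-NLR ~ N(log 2.5, 0.55); response is Bernoulli with
logit = intercept + log(OR)·log-NLR + covariate effects, the intercept set
for a 65% good-or-moderate rate. The seven a-priori covariates (biologic
type, age/10, smoking, disease duration/10, mHAQ, concomitant MTX, number
of prior biologics — count-coded) get small plausible effects recorded in
the truth object.

**What the generator does not emulate.** No batch/processing-order
effects, no gene–gene correlation beyond the shared cell-fraction factor,
no dropout or mapping artefacts, no missing clinical data, and treatment
affects only the neutrophil fraction (no transcriptional reprogramming
within cell types). Passing tests therefore demonstrate correctness of the
estimators under the mixture model, not performance on real cohort data.

## Estimation chain

**Differential expression.** log-CPM with pseudocount 0.5; features
lacking a count ≥ 10 in ≥ 3 samples are dropped before modelling (a
conventional expression filter; the original filter is unpublished). The
mean-variance trend is lowess (span 0.5) of sqrt residual SD on average
log-count; weights are the predicted sqrt-SD at each observation's fitted
log-count to the power −4. Subject blocking for paired contrasts uses
fixed effects (one indicator per subject) — exact and adequate for two
visits, avoiding a correlation model. The variance prior (d₀, s₀²) comes
from method-of-moments on log s² with Newton trigamma inversion; when the
observed spread of log-variances is at or below the sampling spread the
prior df is infinite and all posterior variances equal s₀². One
cross-check test runs the same small matrix through R limma-voom and
requires coefficient agreement to < 0.05 and t-statistic correlation
> 0.98 (the two lowess implementations differ slightly).

**Permutation tests.** Both the concordance and set-level tests recompute
effect vectors under permutation with a closed-form weighted estimator:
for the paired design the subject-blocked WLS coefficient equals the
precision-weighted mean of per-subject MO3−BL differences (collapsed
weights 1/(1/w_BL + 1/w_MO3)); for the two-group design it equals the
difference of weighted group means. The observed statistic uses the same
estimator, preserving exchangeability; voom weights are computed once on
the observed design and held fixed across permutations. Permutation
schemes: within-subject visit sign-flips for paired contrasts (pairing
preserved), label permutation within cohort for group contrasts; two
cohorts are combined by averaging their statistics. p-values use the
add-one estimator and are two-sided on |statistic| — conservative where
the emulated result reports a one-sided-looking positive correlation.
Each dataset's permutation stream is keyed by the master seed plus a
fingerprint of its own sample units, making the two-dataset p invariant to
argument order. Default 1000 permutations (the original count is
unpublished); calibration tests use 99.

**Clinical statistics.** The EULAR thresholds (3.2 / 5.1 / 1.2 / 0.6) are
applied to DAS28-CRP exactly as for the ESR variant — the standard
response matrix. Categorical cohort comparisons use the Yates-corrected
chi-square: it reproduces every p-value reconstructible from the published
cohort table's printed counts (e.g. CCP cohort 1: 0.0081), whereas the
uncorrected Pearson test does not (~0.003). The non-responder drug-level
exclusion uses a strict "below 800 ng/mL" reading; non-responders with a
missing level are kept with a warning by default. Wilcoxon rank-sum tests
are exact for pooled samples ≤ 20 without ties, otherwise normal
approximation with tie correction.

**Cell-type statistics.** References are collapsed to per-cell-type mean
profiles before scoring; the specificity pseudocount is 1 expression unit
(bounds log-ratios for dropout genes); marker sets require score ≥ 2
(4-fold) at the argmax cell type and ≥ 10 genes. The genotype-association
test is plain Pearson chi-square (tables can exceed 2×2), with optional
entry-wise pooling of cohort tables before testing.

**CBC models.** All ratios use natural logs; log NWR − log LWR = log NLR
identically. Paired ratio changes are geometric means with t-intervals on
log differences. Logistic fits are binomial GLM via IRLS (relative
tolerance 1e-8, ≤ 100 iterations) with Wald intervals — consistent with
the symmetric-on-log-scale intervals of the emulated forest plot; complete
or quasi-complete separation (saturating likelihood, diverging
coefficients) raises an explicit error rather than returning spurious
precision. The modelled outcome collapses good-or-moderate vs none.
"Number of prior biologics" is count-coded.

## Numerical and design choices

* Ties in the top-variable ranking break by feature identifier;
  the subset size is round(fraction · n). The pipeline floors the subset
  at 50 features so the concordance test stays defined on small gene
  panels.
* BH-FDR is the exact step-up (monotone accumulated minimum), verified
  against the naive O(n²) definition.
* Degenerate inputs raise errors rather than warnings: zero library
  sizes, rank-deficient designs (offending columns named), constant
  vectors in rank correlation, zero-margin contingency tables,
  sub-minimum permutation counts (< 99).
* All randomness flows from one master seed through named sub-seeds
  (`SeedSequence([master, index])`, reduced below 2³¹).

## Problem sizes

The shipped analyses and tests use 600-gene panels (50 designed markers
per cell type), the study's subject counts (19+21 and 21+15), a
2000-patient CBC population, and 99–1000 permutations; calibration suites
run 100–200 replicates at 150–1000 genes with 8–10 subjects per arm.
These sizes keep every designed effect measurably above its standard
error while the full suite runs in minutes; all are configuration
parameters, not constants.

## Known limitations

* The permutation effect estimator reuses the observed-design voom
  weights; strictly re-deriving weights per permutation would be slower
  and changes p-values negligibly under the null (weights depend on the
  mean-variance trend, not on labels).
* The innate shift scales both innate cell types by a common factor, so
  their designed set effects are proportional; the generator cannot
  represent innate cell types moving in opposite directions.
* Specificity scoring is scale-free only up to the pseudocount; references
  on very different unit scales should be rescaled before scoring.
* The accession-based validation path (running the pipeline on deposited
  count matrices with their metadata) is wired through the user-supplied
  input configuration but is not exercised in tests, which are fully
  synthetic.
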