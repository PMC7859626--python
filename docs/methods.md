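# Methods

This note documents the statistical procedures, the modelling choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about real data.

## Normalization and filtering

Raw HTSeq-style counts are filtered and normalized in a fixed order; the
pipeline runner rejects any other order because the stages do not commute
(the low-normalized-count gene filter depends on factors computed after
the subject filter):

1. genes with a zero count in **over** 1/3 of subjects are removed;
2. subjects with **over** 75% of genes at raw count <= 5 are removed;
3. conditional upper-quartile normalization;
4. genes with **over** 75% of subjects at normalized (pre-log) value <= 3
   are removed.

All prevalence comparisons are strict: a gene with zeros in exactly 1/3 of
subjects, or exactly 75% low values, is retained.  Each filter is
idempotent on its own output.

The conditional upper quartile UQ_s is the 75th percentile of subject s's
non-zero counts, computed with linear interpolation between order
statistics (the common "type 7" quantile; the convention is pinned by the
test suite and centralized in `conditional_upper_quartile` so it can be
swapped).  The normalization factor is f_s = UQ_s / mean_s(UQ_s), with
the mean taken over subjects surviving the subject filter, so factors
average to exactly 1 and the conditional UQ of every subject's normalized
values equals the cohort mean UQ exactly.  Normalized values are stored
as log2(x/f_s + 1); pre-log values are recovered lazily rather than held
twice in memory.

Outlier screening by PCA (subjects beyond k = 4 SD on PC1/PC2) is
report-only: there is no defensible numeric rule for automatic exclusion,
so the diagnostic flags subjects for manual review and never drops them.

## Oxygen exposure

Daily noon FiO2 is corrected to an effective inspired fraction for
low-flow nasal cannula delivery, where the cannula stream is diluted by
entrained room air.  The correction uses a shipped, versioned weight x
flow grid (bilinear interpolation) derived from a minute-volume dilution
model: the fraction of inspired gas supplied by the cannula is
min(1, flow / (0.3 L·min⁻¹·kg⁻¹ × weight)), with 0.3 L/min/kg a standard
neonatal inspiratory minute volume.  Other support modes pass through
unchanged.  Shipping the grid as data rather than code keeps the table
swappable for an institution's own conversion chart.

Cumulative oxygen utilization is, by default, the daily sum of
(effective FiO2 − 0.21) over days 1..14 (or 28): area above room air in
FiO2-excess·days.  The convention is a named strategy
(`AUC_CONVENTIONS`) so a pressure- or mode-weighted integrand can be
slotted in; the default deliberately ignores applied pressure, which
preserves the ordering of exposure severity and is fully testable.
Missing flowsheet days are carried forward up to 2 days, after which they
fall back to room air with a warning — a conservative choice that can
only underestimate exposure.

Outcome labels are pure functions: BPD-Shennan (oxygen at 36 wk PMA,
birth weight < 1500 g, otherwise not-applicable), physiologic BPD
(>= 28 *not necessarily consecutive* days above room air, then a failed
room-air challenge; eligible-but-unchallenged subjects are not-assessed),
and PRD (>= 2 of 4 caregiver surveys with >= 1 positive domain).  A PRD
"no" additionally requires that the positives plus the still-missing
surveys cannot reach two — with fewer completed surveys the label stays
"missing" rather than asserting absence.  The two BPD definitions may
disagree and are never coerced.

## Univariate screens

All three screens default to an FDR threshold of 0.1, matching the
thresholds under which the per-screen gene counts are reported; the run
manifest records the configured value so nothing is hard-coded.

* **Oxygen correlation** — per-gene Spearman rank correlation (midranks,
  then Pearson on ranks) of log2 expression with Oxygen_AUC14, t-
  approximation p-values, Benjamini–Hochberg q-values.  Fold changes are
  annotated between the above-median and at-or-below-median exposure
  halves so the direction column always matches the fold-change sign.
* **SAM-Seq-style test** — operates on raw counts of the retained
  genes/subjects.  Every subject is Poisson down-sampled to the minimum
  sequencing depth (20 resamples by default; if depths are already equal
  the resampling is skipped as it would only add noise), the
  tie-corrected standardized Wilcoxon rank-sum statistic is averaged over
  resamples, and significance is assessed against a label-permutation
  null (1000 permutations by default) via the median FDR: for each
  threshold, the median over permutations of the null exceedance count
  divided by the observed call count, made monotone step-up.
* **GAB-adjusted LRT** — per gene, logistic outcome ~ GAB (null) versus
  outcome ~ GAB + log2 expression (full); the statistic
  2·(ℓ_full − ℓ_null) is referred to χ²(1).  Fits run as one batched
  Newton iteration across all genes (a (G, p, p) solve per step) with
  damped steps; separation or non-convergence falls back to a small
  ridge penalty (λ = 10⁻³) and is flagged per gene.  Fold change is the
  log2 ratio of per-group medians of pre-log normalized values with a
  pseudocount of 1.

Wilcoxon p-values use the midrank normal approximation with a 0.5
continuity correction for n > 25, and exact enumeration of the rank-sum
null (a counting recurrence on the largest observation) at small n
without ties.

## Classifiers

**Screened PC (BPD).**  Genes are screened by two-sided Wilcoxon p <
alpha; PC1 of the survivors is computed on correlation scale (unit gene
variance) by default — covariance scale is available — with one
prune-and-refit pass dropping loadings below 10% of the maximum
magnitude; the loading vector is unit-norm with the sign fixed so the
loading sum is positive.  A logistic model predicts the outcome from the
PC1 score (optionally plus GAB; with adjustment, the screen residualizes
gene ranks on GAB ranks before testing).  The threshold alpha is chosen
from {0.001, 0.005, 0.01, 0.05, 0.10} by stratified inner CV (10-fold,
3 repeats by default) on held-out AUC, ties to the smaller alpha;
selection is restricted to thresholds that leave at least one survivor
on the refit data, and only a grid with no survivors anywhere errors.

**Pathway eigengenes (PRD).**  Each GMT gene set present in the matrix is
reduced to its PC1 score ("eigengene", no pruning); genes in no pathway
drop out of this analysis, genes in several contribute to each.  Pathway
scores are screened by logistic LRT at p < alpha and a model of k
pathways is built by greedy forward selection on log-likelihood gain (or
by L1-penalized logistic regression over a penalty grid).  The pair
(alpha, k) is chosen jointly by bivariate inner CV on pooled held-out
AUC; ties prefer fewer pathways, then the larger (more stringent) alpha.
Pathway PC1s are computed inside training folds by default (leakage-safe);
a global-PC mode exists for sensitivity analysis only.  GAB adjustment is
off by default for the PRD recipe and on-able by flag.  The fitted model
reports the selection order, per-pathway logistic coefficients (log odds
ratios of the unit-norm eigengene scores), and — as descriptive
annotation only — per-gene odds ratios from univariate logistic fits of
the outcome on each standardized gene.

**Honest evaluation.**  Both classifiers report a naive AUC (in-sample
predictions of the full-data refit) next to a nested CV-AUC in which the
*entire* selection procedure (screening threshold, pathway count, PC
fits) reruns inside every outer training fold and held-out probabilities
are pooled into one ROC.  AUC is the tie-corrected Mann–Whitney
statistic (verified against a brute-force pairwise oracle in the tests).
On pure-noise cohorts the naive AUC is heavily inflated (≈ 0.9) while
the nested CV-AUC stays at chance — the reason the reporting layer
always prints the pair.

## Synthetic cohorts

The generator's defaults are the study conditions of the profiled cohort:
145 subjects of whom 72 are born < 29 weeks; ~13,455 expressed genes;
per-subject depth factors log-normal with σ = 0.36 (sequencing depth
9.93 ± 3.69 M reads, CV ≈ 0.37); BPD prevalence 34/72 in the < 29 wk
subgroup; PRD prevalence 70/116 with ~11% of subjects missing PRD;
~3.7% signal genes at log2FC 0.8 (nearly all observed fold changes were
below 2).  Counts are negative-binomial (gamma–Poisson, dispersion 0.08)
around log-normal baseline means, with a per-pathway latent factor
inducing the configured within-pathway correlation on the log scale and
planted genes shifted by signal_log2fc in outcome-positive subjects.
BPD and PRD are assigned by logistic links in gestational age whose
slopes (0.3/wk and 0.10/wk) reproduce the observed between-group GAB
gaps (~0.8 wk and ~2.6 wk) and whose intercepts are solved by bisection
so the marginal prevalence matches the configuration exactly in
expectation.  Oxygen traces follow a declining-exponential FiO2
trajectory whose amplitude grows with prematurity and BPD, floored at
room air; term subjects without BPD stay on room air.  No claim of
clinical realism is intended beyond these monotone links.

What the generator does **not** emulate: batch or library-preparation
effects, FACS purity or RNA-quality variation, realistic CD8+ T-cell
co-expression beyond block correlation, and gene-level mean–dispersion
trends.  Passing recovery tests therefore demonstrates that the
machinery finds structure it is pointed at under the assumed model — not
that it would recover biology from a confounded real cohort.

Every cohort serializes a versioned ground-truth record (schema version
1: planted genes, effect sizes, signal pathways, full configuration) so
recovery tests parse no logs, and fixture sets round-trip exactly
(counts as TSV and MatrixMarket with name sidecars, metadata and
flowsheet TSVs, GMT gene sets, SHA-256 manifest).

## Problem sizes used in the validation suites

The calibration and recovery suites choose sizes that make the checks
statistically meaningful while keeping the default test run quick:

* screen null calibration: 13,455 genes × 72 subjects, 20 seeds
  (SAM-Seq at 100 permutations per seed — the permutation count affects
  p-value resolution, not the call-rate calibration being tested);
* nested-CV null calibration: 2,000 genes (200 pathways for the pathway
  model) × 72 subjects, 3 seeds, 5 outer × 5 inner folds;
* sPCA recovery: 50 planted genes at log2FC 1 among 2,000, n = 72,
  10 seeds; pathway recovery: one planted 10-gene pathway among 200
  nulls, n = 300, 10 seeds.

## Known limitations

* The oxygen-utilization integrand ignores applied pressure and support
  mode beyond the cannula dilution correction; a weighted variant must
  be registered as a strategy by the user.
* The effective-FiO2 grid is a dilution model, not a transcription of
  any hospital's chart.
* Exact Wilcoxon p-values are only used at n <= 25 without ties; with
  ties the midrank normal approximation is used at every n.
* The per-gene odds-ratio column of the pathway model is a univariate
  annotation and must not be read as a multivariable effect.
* LASSO selection uses liblinear's coordinate descent; coefficients at
  very weak penalties can differ from an unpenalized fit in the last
  digits.
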