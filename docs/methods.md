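# Methods

This note records the modelling choices behind `tallgc`: what the
synthetic cohorts emulate, how each stage is defined, the defaults and
their units, and what the tests do and do not demonstrate about real
patient data.

## Synthetic cohorts (`tallgc.simulate`)

The generator emulates diagnostic bone-marrow expression cohorts of
pediatric T-ALL patients labelled relapse (R) or continuous complete
remission (CCR).

**Expression.** Per-gene log2 intensities are Gaussian and then
exponentiated, matching RMA conventions (linear intensities are what the
reference expression tables print, log2 is what every analysis step
uses). Gene baselines are drawn from
N(`base_log2_mean` = 8, `base_log2_sd` = 1.5); per-sample noise is
N(0, `noise_sd` = 0.7) on the log2 scale — a typical spread for RMA
summaries. A planted gene with linear fold change *f* between class
means is produced exactly by shifting the R-class log2 mean by log2 *f*
(both classes share the log-scale variance, so the linear-mean ratio is
*f*). The default planted signature is the five classifier genes at
their array fold changes (ABTB2 1.34, IL7R 0.54, LGALS8 0.85,
PLAC8 0.54, FAM13A1 0.83). Genes are independent within class by
default; the generator does not model within-signature covariance (not
characterised in the source material), probe-level noise, or chip
spatial artefacts.

**Design.** Defaults describe a training-style cohort: `n_patients` = 50
with `relapse_fraction` = 0.44 (22 R / 28 CCR, drawn as a fixed split in
random order). Cohorts with fewer than two samples in either class are
rejected.

**Survival.** Relapse times are log-normal with the configured median
(1.3 y), with the log-scale σ set so the configured range (0.2–3.8 y)
spans ~99 % of the mass, then resampled into the range; the induced
median shift is ~3 %, inside the 10 % recovery tolerance the tests
check. CCR censoring times are uniform on the follow-up range
(3.3–9.2 y, median ≈ 7.3). `event == 1` exactly for relapse patients —
relapse-free survival measured from diagnosis, censored at last
follow-up. Distribution families are this package's choice; only
medians and ranges were available to match.

**Covariates.** Age, WBC and sex are drawn to sit inside the reported
clinical ranges (age clipped normal 12.5 ± 4.5 y on [1.8, 18]; WBC
log-normal around 170 ×10⁹/L; 84 % male) and carry **no** outcome
signal, mirroring the finding that none of them was significantly
associated with outcome. They exist so Cox/stratification code paths
have realistic inputs.

**Cross-assay re-measurement.** `emulate_requantification` models
qRT-PCR (or cross-platform) re-measurement: per gene, on the log2 scale,
output = r·z + √(1−r²)·ε mapped back through the gene's own mean/sd, so
the expected per-gene Pearson r equals `target_r` (default 0.92, the
IL7R array/qRT-PCR correlation) and rank structure is preserved in
expectation. Constant genes are passed through, flagged in
`attrs["constant_genes"]`. Platform bias elsewhere is modelled as a
per-gene multiplicative factor 2^N(0, `platform_shift`) — the simplest
model consistent with systematic probe-level differences between chip
generations.

## Gene ranking (`tallgc.ranking`)

`rank_genes` fits a `RandomForestClassifier` (defaults: 1,000 trees,
√p features per split, fixed seed) on per-gene z-scored log2 expression
and scores genes by the classical Breiman mean decrease in accuracy: for
each tree, the accuracy on its own out-of-bag samples before vs. after
permuting the gene's column, averaged over all trees and `n_repeats` = 5
permutations. Two implementation notes:

- Out-of-bag, not training-set, accuracy is essential: a fully grown
  forest reproduces its training labels even after single-feature
  permutation, which zeroes every training-set score.
- Only trees that split on a gene can change their predictions, so only
  those are re-evaluated — this makes 1,000 genes × 1,000 trees a
  few-second operation.

Negative mean drops are permutation noise and are floored at 0.
Zero-variance genes score 0 and rank last; remaining ties break by gene
id (deterministic reruns, at the cost of a lexicographic order inside
tie blocks). z-scoring makes the ranking exactly invariant to per-gene
affine transforms of log2 expression.

`apply_shortlist` keeps the top `top_n` = 500 genes minus (a) probe ids
whose leading integer is ≥ `b_chip_id_threshold` = 222000 — the numeric
id range of the HG-U133B predecessor chip; the cutoff is a convention,
not documented in the source material, hence overridable or replaceable
by an explicit annotation — and (b) genes below
`min_mean_expression` = 50 linear units. The floor is a deliberately
transparent stand-in for the original (unpublished) qRT-PCR
detectability algorithm; it preserves the pipeline shape, not the exact
membership of the original 57-probe shortlist, which cannot be
reproduced without the original cohort.

## Signature search (`tallgc.search`)

A combination's score is r² = corr²(PC1 scores, 0/1 labels), where PC1
is the leading eigenvector of the covariance of the tuple's z-scored
log2 expression. Genes are z-scored first because otherwise PC1 is
dominated by high-variance genes, defeating combination ranking; a side
effect is affine invariance of r². The PC sign is oriented toward the
first gene (pure convention; r² is sign-invariant).

Exhaustive search exploits the identity that for z-scored genes the PC1
of a subset is the leading eigenvector of the k×k submatrix of the full
correlation matrix C, and r² = (vᵀb)² / ((n−1)λ·SS_y) with b = Z·ỹ
precomputed. Combinations are scored in batches with numpy's stacked
`eigh`; C(57, 5) ≈ 4.19 M tuples complete in ~20 s on one core. If the
number of combinations exceeds `max_evals` the search raises rather than
silently truncating. Beam search (default width 50) is available for
larger shortlists; its best score is bounded by the exhaustive optimum
and coincides with it on clearly planted cases.

Because many tuples reach similar r², the final selection re-checks the
top `top_t` = 100 combinations with a logistic fit and picks the best
training accuracy (`select_best_by_accuracy`), mirroring the original
two-stage selection.

## Outcome models (`tallgc.models`)

Maximum-likelihood logistic regression on z-scored log2 expression;
probability ≥ 0.5 ⇒ R, with ties at the cutoff classified R
(conservative toward detecting relapse; configurable). If the fitted
direction strictly separates the classes the unpenalised likelihood has
no maximum; the fit falls back to ridge with λ = 1e-4 on standardized
features and sets `separation_flag` (needed routinely for k = 5,
n ≈ 34 cohorts). The training scaler travels with the model so frozen
application to other cohorts is defined.

Metrics are percentages rounded half-up to integers in formatted output
(matching the reference panel's style); full precision is kept
internally. The two-sided Fisher exact test uses the point-probability
method (scipy); the tests verify it against full hypergeometric
enumeration with exact binomial coefficients.

`confusion_from_metrics` inverts a printed panel row: it scans all
integer tp (resp. tn) whose rounded percent sensitivity (specificity)
matches the printed value and errors unless the solution is unique. All
thirteen reference panel rows have unique reconstructions, which is what
makes the pooled "Combined" rows and combined p-values exactly
recomputable.

The combined cross-cohort p is the Fisher exact test on the
element-wise pooled 2×2 table. This reading reproduces the printed
magnitudes (1.5e-9; 1.2e-4 excluding training), whereas Fisher's-method
combination of per-cohort p-values does not; the latter is still
available via `combined_p(..., method="fisher-method")`.

## Survival (`tallgc.survival`)

lifelines provides the product-limit estimator, the two-group log-rank
test (χ², 1 df) and Cox partial likelihood with Efron tie handling (its
default; the source material is silent on ties). Tertiles split at the
empirical 33.3/66.7 percentiles with boundary ties assigned to the lower
tertile (deterministic). Formatted p-values below 1e-4 print as
"<0.0001"; raw values are kept. Monotone-likelihood Cox fits are
flagged, not hidden.

## Enrichment (`tallgc.gsea`)

Weighted KS statistic with default exponent w = 1 (the classic
"weighted" GSEA statistic): hits advance by |score|ʷ normalized by the
in-set total, misses retreat by 1/(N − m); ES is the signed extremum of
the running sum. A set covering the whole list scores 0 (no misses to
deviate from). The desk-scale null permutes set membership on the fixed
ranked list (default n_perm ≥ 100); a phenotype-permutation null
(re-ranking genes by signal-to-noise under permuted labels,
`phenotype_null_rankings`) is available when a cohort is supplied —
standard GSEA defaults to phenotype permutation, so both are offered and
labelled. Nominal p is the same-sign tail fraction with a resolution
floor of 1/n_perm (flagged `below_resolution`); NES divides ES by the
mean same-sign null magnitude; FDR q is the pooled null-to-observed NES
tail-fraction ratio, clipped to [0, 1] and monotonized within each sign.
Significance defaults are FDR < 0.25 and nominal p < 0.001. Leading edge
= set members at or before the running-sum peak (after the trough for
negative ES); `pathway_classifier` hands those genes to the logistic
fit. The original leading-edge gene lists (7 NFκB, 12 Wnt/Ca²⁺/cGMP and
14 cell-adhesion genes) are carried as fixture metadata only; they are
not reproducible without the original cohort.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use sizes chosen to give stable verdicts at
interactive runtimes: 20 seeds for search/tertile recovery, 10–20 for RF
recovery, 1,000 simulations for log-rank type-I error, 200 runs ×
200 permutations for p-uniformity, 10 × 50 sets for the all-null FDR
check, and 1,000 random tables for the Fisher oracle. The synthetic gene
universe is 60–1,000 genes rather than the 54,675 probe sets of a full
chip; the planted-signal structure, not the universe size, is what the
statistical claims depend on.

## What passing tests do and do not show

The suite demonstrates internal correctness (oracle agreement for PCA,
Fisher, KM, ES; exact reconstruction of the published panel) and
statistical sanity on data that match the generator's assumptions
(independent log-normal genes, clean labels, log-normal relapse times).
It does not show that the pipeline's discovered signatures generalize on
real cohorts — batch effects, correlated gene modules, label noise,
induction-failure heterogeneity and platform-specific probe behaviour
are all outside the generator — and the reference hazard ratios and
survival curves are format references only, since they depend on the
unavailable patient data. The literal five-gene membership is likewise
not a recovery target; what is tested is that the machinery finds
planted signatures of comparable strength under comparable sample sizes.
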