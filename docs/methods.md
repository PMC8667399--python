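# Methods

This note documents the models behind `loyprs`, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical conventions a user should know before trusting or changing a
parameter.

## LOY from array intensities

### The mLRRY statistic

The Log R Ratio (LRR) of an array probe is the logged ratio of observed to
expected intensity; copy-number loss in a fraction of cells depresses it.
For each sample we take the **median** LRR over the probes flagged as
male-specific region of chromosome Y (MSY) — 488 probes by default — with
the midpoint convention for even counts. The median (rather than the mean)
makes the statistic robust to individual failed probes. Probes with missing
values are ignored; a sample with zero usable MSY probes is unscorable and
propagates as a missing call rather than a zero.

### Calling threshold from an experimental-error null

In a males-only cohort there is no female technical control for the MSY
probes, so the technical-noise distribution must be learned from the cohort
itself. We assume that (i) unaffected men form the dominant mode of the
mLRRY distribution and (ii) technical error is symmetric around that mode,
while true LOY only pushes values left. The threshold construction:

1. estimate the mode by Gaussian kernel density estimation (Silverman's
   plug-in bandwidth) on a 4096-point grid;
2. treat the deviations of the observations **at or above** the mode as one
   half of a symmetric null;
3. take the lower `percentile` (default 0.005, the 0.5th percentile) of the
   symmetrised null: `threshold = mode − q_{1−2·percentile}(deviations)`.

For pure Gaussian noise of spread σ this converges to mode − 2.576 σ. The
estimate is insensitive to left-tail contamination by construction (only
the right flank enters), which the tests verify with a 25 % contaminated
mixture. A fixed threshold (e.g. −0.06 LRR) can be configured instead to
replicate a known operating point. Degenerate inputs (all values equal)
return that value with a warning; below 100 samples a warning notes the
null is poorly determined.

The binary call uses a **strict** inequality, mLRRY < threshold: a sample
sitting exactly on the threshold is not called.

### From mLRRY to the fraction of cells with LOY

If a fraction *f* of cells has lost the Y, the expected MSY intensity ratio
is (1 − f/2)/1 per DNA amount... in practice array response is compressed,
so we model the observed statistic as

    mLRRY = c · log2(1 − f),    inverted as    f = 1 − 2^(mLRRY / c),

with a dimensionless response factor *c* ∈ (0, 1], default **0.46**. The
default is calibrated so that the operating pair (mLRRY = −0.06 → f = 8.6 %)
holds; *c* is configurable and recorded in the output metadata. Positive
mLRRY values clamp to f = 0 (a proportion cannot be negative), making the
conversion continuous at 0 and strictly decreasing below it.

## LOY from WGS read depth

An unaffected diploid male carries one Y per genome, so expected MSY
coverage is half the autosomal coverage. With mosaic fraction *f*:

    y_log2_ratio = log2( mean MSY count / (0.5 · mean autosomal count) ),
    f = 1 − 2^(y_log2_ratio),  clamped to [0, 1].

Windows are consumed as precomputed counts; segmentation, GC correction and
breakpoint calling are the business of upstream copy-number tooling and are
out of scope. The window aggregator is the mean by default (the simulated
Poisson windows are outlier-free); real data would prefer the median, which
is available via `agg="median"`. Array/WGS concordance is the Pearson
correlation of the paired per-sample fraction estimates, with missing
samples excluded and counted.

## Polygenic risk score

The PRS is the plain weighted sum Σ_v β_v d_iv of effect-allele dosages
with log-odds-ratio weights — deliberately without shrinkage, p-value
thresholding or LD clumping. Construction steps:

* **Variant QC.** Call rate must *exceed* 0.90 (a rate of exactly 0.90
  fails the "> 90 %" rule); the Hardy–Weinberg exact p must be ≥ 1e-6
  (threshold conventional for imputed array data, configurable); imputation
  r² must be ≥ 0.3 (r² < 0.3 is removed, exactly 0.3 is retained). The HWE
  test is the two-sided exact test conditioning on allele counts,
  enumerating all heterozygote counts of matching parity and summing the
  probabilities of configurations no more likely than the observed one.
* **Allele alignment.** Variants are matched to the dosage file by id with
  a chrom/pos cross-check (mismatch ⇒ warn and drop). Where the counted
  allele is the score file's *other* allele the effective dosage is
  2 − dosage; incompatible allele pairs are dropped and counted. Ambiguous
  A/T and C/G pairs are never generated, so strand flips cannot masquerade
  as effect/other swaps.
* **Missing dosages** are imputed at twice the effect-allele frequency
  (the convention of standard score-file tooling), configurable to a drop
  policy; a sample missing every variant gets a missing score. On new
  samples `PRSScorer` reuses the frequencies stored at fit time.
* **Standardisation and grouping.** Z-scores have cohort mean 0 and SD 1.
  Risk groups are cut by **rank**, not by score quantiles, so the
  20 / 60 / 20 split is exact under ties (stable input order breaks ties):
  the lowest `round(0.2 n)` scores are "low", the highest `round(0.2 n)`
  "high". At n = 5131 this yields 1026/3079/1026.

## Association statistics

* **Logistic models** are fitted by IRLS (statsmodels GLM, binomial family)
  with convergence tolerance 1e-8 and at most 25 iterations. Standard
  errors are Wald; 95 % CIs use z = 1.96 on the log-odds scale and
  exponentiate to odds ratios. Separation (any |coefficient| > 15 on the
  log-odds scale) and rank deficiency raise errors naming the offending
  terms rather than returning unstable estimates. Profile-likelihood CIs
  are out of scope.
* **Smoking and alcohol** enter the models as *current vs never/former*
  indicators; the three-level coding is kept only for the descriptive
  baseline table.
* **ANCOVA** of the PRS by LOY status is the linear model
  prs_z ~ loy + age + smoking + alcohol; the reported p is the LOY term's
  and adjusted group means are evaluated at the covariate means. With no
  covariates it reduces exactly to the pooled-variance two-sample t-test.
* **Baseline table**: Welch t-test for age (rather than pooled; documented
  choice), Pearson chi-square without continuity correction for
  categoricals (counts are large; correction configurable), column
  percentages with the column n as denominator at one decimal.
* **Wilcoxon rank-sum** uses the normal approximation with tie correction;
  a zero-variance pooled sample returns p = 1.
* **ROC/AUC** uses the Mann–Whitney midrank identity; variance and CIs come
  from DeLong structural components. **DeLong's test** for two correlated
  AUCs on the same samples uses the paired structural-component covariance;
  identical prediction vectors return z = 0, p = 1 by convention. The AUC
  models are fitted and evaluated in-sample, matching the usual reporting
  of cohort prediction studies; no cross-validation is applied.
* **Age strata** are [70, 75), [75, 80), [80, ∞) — left-closed, so age 75.0
  belongs to 75–79 and 80.0 to 80+. Within strata age is excluded from the
  design; a stratum without both outcomes or with fewer than two PRS groups
  is reported as unestimable, never silently dropped.

## The synthetic cohort

The generator's defaults are the study conditions the pipeline targets:
5131 men aged 70+, 488 MSY probes, 156 score variants of which 123 survive
QC, 30× WGS coverage on a 947-man subset.

* **Covariates.** Age bins 70–74 / 75–79 / 80–84 / 85+ with weights
  0.58 / 0.26 / 0.11 / 0.05 (uniform within bin; the open 85+ bin is
  sampled on [85, 92)), giving mean age ≈ 75.7. Smoking
  never/former/current at 43.9 / 52.6 / 3.5 %, alcohol 9.0 / 5.7 / 85.3 %,
  treatment randomised 50/50, BMI categories at their cohort shares.
* **Generative LOY model.** logit P(LOY) = β₀ + β_age(age − 75) + β_prs z +
  β_smoke·current + β_alc·current with β_prs = ln 1.74, β_age = ln 1.11,
  β_smoke = ln 2.13, β_alc = ln 1.21. β₀ = −1.3598 was calibrated once,
  before any downstream checking, to give ≈ 27.2 % overall prevalence under
  the default covariate distributions; the implied age gradient is ≈ 21 /
  30 / 41 / 56 % across the four bins. The true PRS entering the model is
  the weighted sum over the QC-passing variants (so the generative effect
  refers to a score the pipeline can actually reconstruct), Z-standardised
  within the cohort.
* **Mosaic fractions.** Affected men draw f from Beta(1.2, 3) rescaled to
  [0.09, 0.80] — right-skewed, mostly above the calling threshold's 8.6 %
  operating point; unaffected men have f = 0 (configurable jitter). The
  fraction law of real cohorts is not identified by a calling threshold
  alone; this is a documented stand-in, not an inference.
* **Genotypes.** Effect-allele frequencies ~ U(0.05, 0.95), hard HWE
  genotypes emitted as dosages, per-variant missingness ~ U(0, 0.03),
  imputation r² ~ U(0.40, 1.00) for passing variants; a 33/156 share is
  forced to r² ~ U(0.05, 0.25) so exactly 123 survive the r² < 0.3 filter.
  30 % of variants count the non-effect allele to exercise alignment.
  Weights ~ N(0, 0.06); no linkage disequilibrium is simulated.
* **Arrays and WGS.** MSY probes are Gaussian around c·log2(1 − f) with
  probe noise SD 0.3 (so the per-sample median has SE ≈ 1.2533·0.3/√488 ≈
  0.017 LRR); 100 autosomal reference probes are centred at 0. WGS windows
  are Poisson with autosomal mean 30 and MSY mean 30(1 − f)/2, 500 + 200
  windows per sample.

**What passing tests show — and don't.** The generator draws independent
probes, independent variants, and exactly Gaussian/Poisson noise. Real
arrays have correlated probe noise, GC and batch structure; real genotypes
have LD; real WGS has mappability and GC coverage waves. Recovery results
(fraction MAE ≈ 1 percentage point, CI coverage of the generating odds
ratio) therefore demonstrate the correctness of the estimators under their
stated model, not field performance on a real cohort. Quantities that
depend on a specific real cohort's composition — the exact quintile
contrast, the exact AUCs, the exact concordance r — are reproduced in
direction and approximate magnitude only.

## Problem sizes and determinism

A single integer seed drives one master `SeedSequence`; each generator
stage uses a deterministic spawn key, so stages can be regenerated
independently and identical seeds give identical datasets. The test suite
runs cohorts of 400–5131 men; the acceptance script uses one default-scale
pipeline run plus five in-memory cohort replicates (odds ratios are
combined by geometric mean, AUCs arithmetically) to damp single-cohort
Monte-Carlo noise, 150 000 draws for the threshold null, and 5000 samples
for fraction recovery — sizes at which every reported quantity's
Monte-Carlo error is well inside the differences that matter.

## Known limitations

* No B-allele-frequency-based mosaicism detection, partial-Y events, or
  longitudinal LOY expansion modelling.
* The mLRRY→fraction conversion and the reflected-null construction are
  documented conventions with configurable parameters, not reproductions of
  any proprietary array pipeline.
* Control-FREEC-style copy-number machinery (GC correction, segmentation)
  is not reimplemented; WGS windows enter as precomputed counts.
* PRS refinement (shrinkage, thresholding, LD clumping) is deliberately
  absent.
* The quintile cut stores score cut-points at fit; applying them to a new
  cohort assumes the training cohort's score distribution.
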