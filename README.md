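# loyprs

Mosaic **loss of chromosome Y (LOY)** is the most common acquired aneuploidy
in ageing men: a growing fraction of their circulating white blood cells
loses the Y chromosome, and carriers are at elevated risk for cancer,
cardiovascular disease, Alzheimer's disease and all-cause mortality.
`loyprs` is a tested, reusable pipeline for the genetic-epidemiology
analysis of LOY in a male cohort:

* **LOY calling from SNP-array intensities.** For each man the package
  computes **mLRRY**, the median Log R Ratio over the male-specific-region
  probes of chromosome Y (488 by default). mLRRY ≈ 0 in unaffected men and
  goes negative with mosaicism. A calling threshold is derived from an
  experimental-error null (reflect the observations above the distribution
  mode, take the 0.5th percentile), or fixed (e.g. −0.06). The fraction of
  cells with LOY is recovered as *f* = 1 − 2^(mLRRY/*c*) with array response
  factor *c* = 0.46, which maps mLRRY = −0.06 to 8.6 % of cells.
* **Polygenic risk score (PRS).** A weighted sum of effect-allele dosages,
  PRS_i = Σ_v β_v · d_iv, with GWAS log-odds-ratio weights β_v, after
  variant QC (call rate > 90 %, Hardy–Weinberg exact test, imputation
  r² ≥ 0.3) and allele alignment. Scores are Z-standardised and cut by rank
  into quintile risk groups (low = bottom 20 %, high = top 20 %).
* **Association and prediction.** Baseline-table tests, ANCOVA of the PRS
  distribution by LOY status, logistic models for LOY on the PRS (per SD and
  by risk group) adjusted for age, smoking and alcohol, age-stratified odds
  ratios, and ROC/AUC model comparison with DeLong's test for correlated
  AUCs.
* **WGS validation.** A read-depth LOY estimate,
  log2( mean MSY depth / (0.5 · mean autosomal depth) ), and its Pearson
  concordance with the array-derived estimate.
* **Synthetic cohorts with ground truth.** A seeded generator produces
  covariates, HWE dosage genotypes with a score file, probe-level LRR
  matrices and Poisson WGS depth windows under a known generative logistic
  model for LOY, so every stage is testable end to end without any data
  download.

`LOYCaller` and `PRSScorer` are scikit-learn style estimators
(`fit`/`transform`, fitted attributes with trailing underscores) and compose
with sklearn tooling; the remaining statistics are statsmodels-backed
functions returning result objects.

## Worked example

Simulate a default cohort (5131 men aged 70+, 156 score variants of which
123 pass QC, a generating per-SD odds ratio of 1.74) and run the full
analysis:

```bash
loyprs simulate --seed 42 --out demo/data
loyprs run --seed 42 --data demo/data --out demo/results
loyprs report --out demo/results
```

The run report (abridged) prints:

```json
{
  "association": {
    "loy_prevalence_pct": 27.3,
    "per_sd_or": 1.735,
    "per_sd_or_ci": [1.620, 1.859],
    "quintile_middle_or": 2.58,
    "quintile_high_or": 4.85,
    "ancova_p": 4.7e-60,
    "roc": {
      "auc_base": 0.640,
      "auc_full": 0.698,
      "delong_p": 6.5e-16
    }
  },
  "concordance": {"pearson_r": 0.990, "n": 947},
  "counts": {"n_scored": 5131, "n_variants_pass_qc": 123}
}
```

Reading these numbers: 27.3 % of the simulated men are called LOY
(mLRRY below the estimated threshold). Each standard deviation of the PRS
multiplies the odds of LOY by 1.74 (fitted 1.735, CI 1.62–1.86) after
adjusting for age, smoking and alcohol; men in the top PRS quintile have
4.9-fold the odds of the bottom quintile. Adding the PRS to the
age + smoking + alcohol prediction model raises the AUC from 0.640 to 0.698
(DeLong p ≈ 10⁻¹⁶), and the array- and WGS-derived cell-fraction estimates
agree at r = 0.99 on the 947-man sequenced subset. Per-stage tables
(`loy_calls.tsv`, `prs.tsv`, `table1/2/3.tsv`, `age_stratified.tsv`,
`roc_report.json`, `concordance.json`) are written next to the report.

The same analysis is available as a library:

```python
from loyprs import LOYCaller, PRSScorer, fit_logistic, simulate_dataset

ds = simulate_dataset(seed=42)
msy = ds.probe_annotation.query("is_msy == 1")["probe_id"]
calls = LOYCaller(msy_probes=msy).fit(ds.lrr.T).transform(ds.lrr.T)
prs = PRSScorer(score_variants=ds.score_file).fit(
    ds.dosages, dosage_meta=ds.dosage_meta
).transform(ds.dosages)
```

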