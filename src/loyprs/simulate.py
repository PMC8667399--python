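"""Seeded synthetic cohorts for the LOY risk-prediction analysis.

The generator emulates the statistical structure the downstream stages
assume, with known per-sample ground truth:

* a cohort of older men (age bins 70-74 / 75-79 / 80-84 / 85+) with smoking,
  alcohol, randomised-treatment and BMI-category covariates;
* biallelic variants in Hardy-Weinberg proportions emitted as dosages in
  [0, 2], with per-variant imputation quality and a matching score file of
  log-odds-ratio weights;
* a generative logistic model for the true LOY indicator driven by age, the
  (standardised) true polygenic score, current smoking and current alcohol
  use; affected men receive a mosaic cell fraction drawn from a rescaled
  Beta law;
* probe-level Log R Ratios whose male-specific-Y (MSY) probe mean follows
  ``response_factor * log2(1 - f)`` for mosaic fraction ``f``, plus Gaussian
  probe noise; autosomal reference probes are centred at zero;
* Poisson read-depth windows where MSY coverage is half the autosomal
  coverage scaled by ``(1 - f)`` (one Y per diploid genome).

A single integer seed drives every stage through deterministic sub-streams,
so any stage can be regenerated independently of the others.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_cohort",
    "generate_genotypes",
    "generate_true_loy",
    "generate_lrr_matrix",
    "generate_wgs_depth",
    "simulate_dataset",
]

#: age bins as [low, high) intervals in years; the last bin is the open-ended
#: "85+" group, truncated at 92 for sampling.
AGE_BINS: tuple[tuple[float, float], ...] = ((70, 75), (75, 80), (80, 85), (85, 92))
AGE_BIN_LABELS: tuple[str, ...] = ("70-74", "75-79", "80-84", "85+")

SMOKING_LEVELS = ("never", "former", "current")
ALCOHOL_LEVELS = ("never", "former", "current")
TREATMENT_LEVELS = ("placebo", "aspirin")
BMI_LEVELS = ("underweight", "normal", "overweight", "obese", "missing")

# non-ambiguous allele pairs only (no A/T or C/G), so strand flips can never
# be confused with effect/other swaps during allele alignment
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))

# stage indices for deterministic sub-streams of the master seed
_STAGES = {"cohort": 0, "genotypes": 1, "true_loy": 2, "lrr": 3, "wgs": 4}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the analysis is designed for:
    5131 men aged 70+, 488 MSY probes, a generative per-SD odds ratio of
    1.74 for the polygenic score, an overall LOY prevalence of about 27%
    rising with age, and 30x WGS coverage for a 947-man subset.
    """

    n_samples: int = 5131
    n_variants: int = 156
    n_msy_probes: int = 488
    n_autosomal_probes: int = 100
    probe_noise_sd: float = 0.3
    #: array response factor c linking mLRRY to cell fraction via
    #: mLRRY = c * log2(1 - f); calibrated so -0.06 corresponds to 8.6% cells
    response_factor: float = 0.46

    # covariate distributions (never / former / current; categorical weights)
    age_bin_weights: tuple[float, ...] = (0.58, 0.26, 0.11, 0.05)
    smoking_probs: tuple[float, ...] = (0.439, 0.526, 0.035)
    alcohol_probs: tuple[float, ...] = (0.090, 0.057, 0.853)
    bmi_probs: tuple[float, ...] = (0.008, 0.210, 0.521, 0.257, 0.004)

    # generative logistic model for the true LOY indicator:
    # logit P = beta0 + beta_age*(age-75) + beta_prs*z + beta_smoke*current
    #           + beta_alc*current
    beta0: float = -1.3598  # calibrated for ~27.2% overall prevalence
    beta_age: float = math.log(1.11)
    beta_prs: float = math.log(1.74)
    beta_smoke: float = math.log(2.13)
    beta_alc: float = math.log(1.21)

    # mosaic fraction given LOY: Beta(a, b) rescaled to [fraction_min,
    # fraction_max]; unaffected men have fraction 0 (plus optional jitter)
    fraction_beta_a: float = 1.2
    fraction_beta_b: float = 3.0
    fraction_min: float = 0.09
    fraction_max: float = 0.80
    baseline_fraction_sd: float = 0.0

    # genotypes / score file
    eaf_range: tuple[float, float] = (0.05, 0.95)
    weight_sd: float = 0.06
    missing_rate_range: tuple[float, float] = (0.0, 0.03)
    r2_pass_range: tuple[float, float] = (0.40, 1.00)
    r2_fail_range: tuple[float, float] = (0.05, 0.25)
    #: share of variants forced to fail imputation QC (r2 < 0.3); the default
    #: reproduces 33 failures out of 156, leaving 123 scored variants
    qc_fail_fraction: float = 33 / 156
    #: share of variants whose dosage file counts the non-effect allele,
    #: exercising allele alignment downstream
    flip_fraction: float = 0.3

    # WGS read-depth windows
    wgs_autosomal_depth: float = 30.0
    n_wgs_msy_windows: int = 200
    n_wgs_autosomal_windows: int = 500
    n_wgs_samples: int = 947

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("age_bin_weights", "smoking_probs", "alcohol_probs", "bmi_probs"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.ndim != 1 or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-8):
                raise ConfigurationError(f"{name} must be non-negative weights summing to 1")
        if len(self.age_bin_weights) != len(AGE_BINS):
            raise ConfigurationError(f"age_bin_weights needs {len(AGE_BINS)} entries")
        if self.n_msy_probes < 1:
            raise ConfigurationError("n_msy_probes must be >= 1")
        if self.probe_noise_sd <= 0:
            raise ConfigurationError("probe_noise_sd must be > 0")
        if not 0 < self.response_factor <= 1:
            raise ConfigurationError("response_factor must be in (0, 1]")
        if not 0 <= self.fraction_min < self.fraction_max <= 1:
            raise ConfigurationError("fraction range must satisfy 0 <= min < max <= 1")
        if self.n_samples < 0 or self.n_variants < 0:
            raise ConfigurationError("sample and variant counts must be non-negative")
        if self.wgs_autosomal_depth <= 0:
            raise ConfigurationError("wgs_autosomal_depth must be > 0")


@dataclass
class SyntheticDataset:
    """Bundle of all generated tables for one seeded simulation."""

    config: SimulationConfig
    covariates: pd.DataFrame
    dosages: pd.DataFrame
    dosage_meta: pd.DataFrame
    score_file: pd.DataFrame
    truth: pd.DataFrame
    lrr: pd.DataFrame
    probe_annotation: pd.DataFrame
    wgs_depth: pd.DataFrame


def _sample_ids(n: int) -> list[str]:
    width = max(5, len(str(max(n, 1))))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the covariate table: one row per man.

    Ages are drawn uniformly within the sampled age bin; smoking and alcohol
    are three-level categoricals; treatment is a 50/50 randomisation.
    """
    rng = _rng(config.seed, "cohort")
    n = config.n_samples
    bins = rng.choice(len(AGE_BINS), size=n, p=np.asarray(config.age_bin_weights))
    lo = np.array([b[0] for b in AGE_BINS])[bins]
    hi = np.array([b[1] for b in AGE_BINS])[bins]
    age = rng.uniform(lo, hi)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=np.asarray(config.smoking_probs))
    alcohol = rng.choice(ALCOHOL_LEVELS, size=n, p=np.asarray(config.alcohol_probs))
    treatment = rng.choice(TREATMENT_LEVELS, size=n, p=[0.5, 0.5])
    bmi = rng.choice(BMI_LEVELS, size=n, p=np.asarray(config.bmi_probs))
    return pd.DataFrame(
        {
            "sample_id": _sample_ids(n),
            "age": age,
            "smoking": smoking,
            "alcohol": alcohol,
            "treatment": treatment,
            "bmi_category": bmi,
        }
    )


def generate_genotypes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw hard genotypes in Hardy-Weinberg proportions as dosages.

    Returns ``(dosages, dosage_meta, score_file)``.

    * ``dosages`` — samples x variants matrix of 0/1/2 counts of the
      *counted* allele, with NaN for missing calls (sample_id index).
    * ``dosage_meta`` — per-variant counted/uncounted alleles, position and
      imputation r2. A configured share of variants counts the non-effect
      allele, and a configured share receives r2 < 0.3 so it fails QC.
    * ``score_file`` — variant_id, chrom, pos, effect_allele, other_allele,
      weight (log odds ratio).
    """
    rng = _rng(config.seed, "genotypes")
    m = config.n_variants
    n = config.n_samples
    variant_ids = [f"rs{100000 + i}" for i in range(m)]
    chrom = rng.integers(1, 23, size=m).astype(str)
    pos = rng.integers(1_000_000, 100_000_000, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    effect = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    other = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    swap = rng.random(m) < 0.5  # which of the pair is the effect allele
    effect, other = np.where(swap, other, effect), np.where(swap, effect, other)

    eaf = rng.uniform(*config.eaf_range, size=m)
    weights = rng.normal(0.0, config.weight_sd, size=m)

    # genotypes as effect-allele counts under HWE
    geno = rng.binomial(2, eaf, size=(n, m)).astype(float) if n else np.empty((0, m))
    miss_rate = rng.uniform(*config.missing_rate_range, size=m)
    if n:
        geno[rng.random((n, m)) < miss_rate] = np.nan

    # orientation of the dosage file: flipped variants count the other allele
    flipped = rng.random(m) < config.flip_fraction
    dosage = geno.copy()
    if n:
        dosage[:, flipped] = 2.0 - dosage[:, flipped]
    counted = np.where(flipped, other, effect)
    uncounted = np.where(flipped, effect, other)

    n_fail = int(round(config.qc_fail_fraction * m))
    fail_idx = rng.choice(m, size=n_fail, replace=False) if m else np.array([], int)
    r2 = rng.uniform(*config.r2_pass_range, size=m)
    r2[fail_idx] = rng.uniform(*config.r2_fail_range, size=n_fail)

    dosages = pd.DataFrame(dosage, index=pd.Index(_sample_ids(n), name="sample_id"), columns=variant_ids)
    dosage_meta = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": pos,
            "counted_allele": counted,
            "uncounted_allele": uncounted,
            "imputation_r2": r2,
            "effect_allele_freq": eaf,
        }
    )
    score_file = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect,
            "other_allele": other,
            "weight": weights,
        }
    )
    return dosages, dosage_meta, score_file


def generate_true_loy(
    covariates: pd.DataFrame, true_prs_z: pd.Series, config: SimulationConfig
) -> pd.DataFrame:
    """Draw the true LOY state from the generative logistic model.

    ``true_prs_z`` must be Z-standardised within the cohort.  Affected men
    receive a mosaic fraction from the rescaled Beta law; unaffected men
    have fraction 0 up to the configured baseline jitter.
    """
    rng = _rng(config.seed, "true_loy")
    z = true_prs_z.reindex(covariates["sample_id"]).to_numpy(dtype=float)
    age = covariates["age"].to_numpy(dtype=float)
    smoke = (covariates["smoking"] == "current").to_numpy()
    alc = (covariates["alcohol"] == "current").to_numpy()
    lin = (
        config.beta0
        + config.beta_age * (age - 75.0)
        + config.beta_prs * z
        + config.beta_smoke * smoke
        + config.beta_alc * alc
    )
    p = expit(lin)
    loy = rng.random(len(p)) < p
    frac = np.zeros(len(p))
    n_loy = int(loy.sum())
    if n_loy:
        raw = rng.beta(config.fraction_beta_a, config.fraction_beta_b, size=n_loy)
        frac[loy] = config.fraction_min + raw * (config.fraction_max - config.fraction_min)
    if config.baseline_fraction_sd > 0:
        frac[~loy] = np.abs(rng.normal(0.0, config.baseline_fraction_sd, size=int((~loy).sum())))
    return pd.DataFrame(
        {
            "sample_id": covariates["sample_id"].to_numpy(),
            "p_loy": p,
            "true_loy": loy.astype(int),
            "true_fraction": np.clip(frac, 0.0, 1.0),
            "true_prs_z": z,
        }
    )


def generate_lrr_matrix(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the probes x samples Log R Ratio matrix and probe annotation.

    MSY probes are centred at ``response_factor * log2(1 - f)`` per sample;
    autosomal probes at 0.  Probe annotation is BED-like (0-based half-open)
    with an ``is_msy`` flag.
    """
    rng = _rng(config.seed, "lrr")
    f = truth["true_fraction"].to_numpy(dtype=float)
    one_minus_f = 1.0 - f
    floor = 1e-6
    if np.any(one_minus_f <= floor):
        warnings.warn(
            "mosaic fraction at or near 1; clamping 1-f at 1e-6 for log2", RuntimeWarning
        )
        one_minus_f = np.maximum(one_minus_f, floor)
    msy_mean = config.response_factor * np.log2(one_minus_f)

    n = len(f)
    n_msy, n_auto = config.n_msy_probes, config.n_autosomal_probes
    values = np.empty((n_msy + n_auto, n))
    values[:n_msy] = msy_mean[None, :] + rng.normal(0.0, config.probe_noise_sd, size=(n_msy, n))
    values[n_msy:] = rng.normal(0.0, config.probe_noise_sd, size=(n_auto, n))

    starts_y = np.sort(rng.choice(np.arange(2_650_000, 28_000_000, 50), size=n_msy, replace=False))
    starts_a = np.sort(rng.choice(np.arange(1_000_000, 200_000_000, 50), size=n_auto, replace=False))
    probe_ids = [f"probeY_{i:04d}" for i in range(n_msy)] + [f"probeA_{i:04d}" for i in range(n_auto)]
    annotation = pd.DataFrame(
        {
            "chrom": ["chrY"] * n_msy + ["chr1"] * n_auto,
            "start": np.concatenate([starts_y, starts_a]),
            "end": np.concatenate([starts_y, starts_a]) + 25,
            "probe_id": probe_ids,
            "is_msy": [1] * n_msy + [0] * n_auto,
        }
    )
    lrr = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=truth["sample_id"].to_numpy())
    return lrr, annotation


def generate_wgs_depth(
    truth: pd.DataFrame, config: SimulationConfig, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Draw Poisson read-depth windows for the WGS subset.

    Autosomal windows have mean ``wgs_autosomal_depth``; MSY windows have
    mean ``depth * (1 - f) / 2`` (one Y chromosome per diploid genome).  By
    default the first ``n_wgs_samples`` men form the sequenced subset.
    """
    rng = _rng(config.seed, "wgs")
    if sample_ids is None:
        sample_ids = truth["sample_id"].head(config.n_wgs_samples).tolist()
    frac = truth.set_index("sample_id")["true_fraction"]
    lam = config.wgs_autosomal_depth
    n_msy, n_auto = config.n_wgs_msy_windows, config.n_wgs_autosomal_windows
    win = 10_000
    msy_start = np.arange(n_msy) * win + 2_650_000
    auto_start = np.arange(n_auto) * win + 1_000_000

    records = []
    for sid in sample_ids:
        f = float(frac.loc[sid])
        msy_counts = rng.poisson(lam * (1.0 - f) / 2.0, size=n_msy)
        auto_counts = rng.poisson(lam, size=n_auto)
        records.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "chrom": ["chrY"] * n_msy + ["chr1"] * n_auto,
                    "start": np.concatenate([msy_start, auto_start]),
                    "end": np.concatenate([msy_start, auto_start]) + win,
                    "region_class": ["MSY"] * n_msy + ["autosomal"] * n_auto,
                    "read_count": np.concatenate([msy_counts, auto_counts]),
                }
            )
        )
    if not records:
        return pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end", "region_class", "read_count"]
        )
    return pd.concat(records, ignore_index=True)


def true_raw_prs(dosages: pd.DataFrame, dosage_meta: pd.DataFrame, score_file: pd.DataFrame) -> pd.Series:
    """Ground-truth raw polygenic score over variants passing default QC.

    Computed in effect-allele orientation directly from the generated
    genotypes, with missing calls imputed at twice the effect-allele
    frequency — the same convention the scoring engine documents — so the
    generative effect size refers to the score the pipeline can actually
    reconstruct.
    """
    meta = dosage_meta.set_index("variant_id")
    weights = score_file.set_index("variant_id")["weight"]
    passing = meta.index[meta["imputation_r2"] >= 0.30]
    total = pd.Series(0.0, index=dosages.index)
    for vid in passing:
        d = dosages[vid]
        if meta.loc[vid, "counted_allele"] != score_file.set_index("variant_id").loc[vid, "effect_allele"]:
            d = 2.0 - d
        d = d.fillna(2.0 * meta.loc[vid, "effect_allele_freq"])
        total = total + weights.loc[vid] * d
    return total


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate the full synthetic dataset for one seed.

    Keyword overrides are applied to a fresh :class:`SimulationConfig` (or a
    copy of the one supplied).
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)

    covariates = generate_cohort(config)
    dosages, dosage_meta, score_file = generate_genotypes(config)

    raw = true_raw_prs(dosages, dosage_meta, score_file)
    sd = raw.std(ddof=0)
    z = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0

    truth = generate_true_loy(covariates, z, config)
    truth["true_prs_raw"] = raw.to_numpy()
    lrr, annotation = generate_lrr_matrix(truth, config)
    wgs = generate_wgs_depth(truth, config)
    return SyntheticDataset(
        config=config,
        covariates=covariates,
        dosages=dosages,
        dosage_meta=dosage_meta,
        score_file=score_file,
        truth=truth,
        lrr=lrr,
        probe_annotation=annotation,
        wgs_depth=wgs,
    )
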