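"""Polygenic risk score (PRS) construction for LOY predisposition.

The score is a weighted sum of effect-allele dosages, the weights being
GWAS log odds ratios from a score file.  Construction follows the usual
array workflow: per-variant QC (call rate > 90%, Hardy-Weinberg exact test,
imputation r2 >= 0.3), alignment of the dosage file's counted allele to the
score file's effect allele, the weighted sum itself, Z-standardisation
within the cohort, and quintile risk grouping (low = bottom 20%, high = top
20%, middle = the rest).

:class:`PRSScorer` exposes the whole chain as a scikit-learn style
transformer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PRSScorer",
    "ScoreFileError",
    "read_score_file",
    "hwe_exact_test",
    "build_variant_meta",
    "variant_qc",
    "align_alleles",
    "compute_prs",
    "standardize_and_group",
]

SCORE_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]


class ScoreFileError(ValueError):
    """Malformed or inconsistent score file."""


def read_score_file(path) -> pd.DataFrame:
    """Parse and validate a headered TSV score file.

    Required columns: variant_id, chrom, pos, effect_allele, other_allele,
    weight.  Duplicate variant ids, identical allele pairs, or unparsable
    fields raise :class:`ScoreFileError` naming the offending line.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ScoreFileError(f"cannot parse score file {path}: {exc}") from exc
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ScoreFileError(f"score file missing column(s): {', '.join(missing)}")
    df = df[SCORE_COLUMNS].copy()
    # data line i sits on file line i + 2 (1-based, after the header)
    for i, row in df.iterrows():
        line = i + 2
        if row.isna().any():
            raise ScoreFileError(f"line {line}: missing field")
        try:
            int(row["pos"])
        except ValueError as exc:
            raise ScoreFileError(f"line {line}: position {row['pos']!r} is not an integer") from exc
        try:
            w = float(row["weight"])
        except ValueError as exc:
            raise ScoreFileError(f"line {line}: weight {row['weight']!r} is not a number") from exc
        if not np.isfinite(w):
            raise ScoreFileError(f"line {line}: weight must be finite")
        if row["effect_allele"] == row["other_allele"]:
            raise ScoreFileError(f"line {line}: effect and other allele are identical")
    dup = df["variant_id"].duplicated()
    if dup.any():
        first = df.loc[dup, "variant_id"].iloc[0]
        raise ScoreFileError(f"duplicate variant_id {first!r}")
    df["pos"] = df["pos"].astype(int)
    df["weight"] = df["weight"].astype(float)
    return df.reset_index(drop=True)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of matching parity; the p-value is the sum of the
    probabilities of all configurations no more likely than the observed
    one.  Monomorphic variants return p = 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_ref + n_het  # rare-vs-common symmetry handled below
    n_b = 2 * n_hom_alt + n_het
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0

    # log-probability of each possible het count under the exact conditional
    # distribution: P(het) ∝ n! / (hom_ref! het! hom_alt!) * 2^het
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het]
    if obs.size != 1:  # parity mismatch cannot happen with valid counts
        raise ValueError("inconsistent genotype counts")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def build_variant_meta(
    dosages: pd.DataFrame, imputation_r2: pd.Series | None = None
) -> pd.DataFrame:
    """Per-variant QC metrics computed from a hard-dosage matrix.

    Call rate is the non-missing fraction; the HWE p-value is the exact test
    on rounded genotype counts.  ``imputation_r2`` defaults to 1 when not
    supplied (directly genotyped variants).
    """
    records = []
    for vid in dosages.columns:
        d = dosages[vid]
        obs = d.dropna()
        call_rate = len(obs) / len(d) if len(d) else 0.0
        g = np.clip(np.round(obs.to_numpy(dtype=float)), 0, 2).astype(int)
        if len(g):
            hwe_p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        else:
            hwe_p = 1.0
        records.append({"variant_id": vid, "call_rate": call_rate, "hwe_p": hwe_p})
    meta = pd.DataFrame(records)
    if imputation_r2 is not None:
        meta["imputation_r2"] = meta["variant_id"].map(imputation_r2).astype(float)
    else:
        meta["imputation_r2"] = 1.0
    return meta


def variant_qc(
    meta: pd.DataFrame,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
    r2_min: float = 0.30,
) -> tuple[pd.DataFrame, dict]:
    """Apply variant QC filters and report per-filter exclusion counts.

    A variant passes when its call rate exceeds ``call_rate_min`` (strict:
    a rate of exactly 0.90 fails the ">90%" rule), its HWE exact p is at
    least ``hwe_p_min``, and its imputation r2 is at least ``r2_min``
    (variants with r2 < 0.3 are removed; exactly 0.3 is retained).
    """
    meta = meta.copy()
    fail_call = meta["call_rate"] <= call_rate_min
    fail_hwe = meta["hwe_p"] < hwe_p_min
    fail_r2 = meta["imputation_r2"] < r2_min
    meta["qc_pass"] = ~(fail_call | fail_hwe | fail_r2)
    report = {
        "n_variants": int(len(meta)),
        "n_pass": int(meta["qc_pass"].sum()),
        "n_fail_call_rate": int(fail_call.sum()),
        "n_fail_hwe": int(fail_hwe.sum()),
        "n_fail_r2": int(fail_r2.sum()),
        "call_rate_min": call_rate_min,
        "hwe_p_min": hwe_p_min,
        "r2_min": r2_min,
    }
    return meta, report


def align_alleles(
    score_variants: pd.DataFrame, dosage_meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Orient score-file weights onto the dosage file's counted alleles.

    Variants are matched by id with a chrom/pos cross-check.  Where the
    counted allele is the effect allele the dosage is used as-is; where it
    is the other allele the effective dosage is ``2 - dosage``.  Unmatched,
    positionally inconsistent or allele-incompatible variants are dropped
    and counted in the report.
    """
    meta = dosage_meta.set_index("variant_id")
    rows, n_unmatched, n_pos_mismatch, n_incompatible = [], 0, 0, 0
    for _, sv in score_variants.iterrows():
        vid = sv["variant_id"]
        if vid not in meta.index:
            n_unmatched += 1
            continue
        dm = meta.loc[vid]
        if "chrom" in meta.columns and "pos" in meta.columns:
            if str(dm["chrom"]) != str(sv["chrom"]) or int(dm["pos"]) != int(sv["pos"]):
                warnings.warn(
                    f"variant {vid}: chrom/pos mismatch between score and dosage files; dropped",
                    RuntimeWarning,
                )
                n_pos_mismatch += 1
                continue
        counted = dm["counted_allele"]
        if counted == sv["effect_allele"]:
            flip = False
        elif counted == sv["other_allele"]:
            flip = True
        else:
            n_incompatible += 1
            continue
        rows.append({"variant_id": vid, "weight": float(sv["weight"]), "flip": flip})
    aligned = pd.DataFrame(rows, columns=["variant_id", "weight", "flip"])
    report = {
        "n_aligned": len(aligned),
        "n_unmatched": n_unmatched,
        "n_pos_mismatch": n_pos_mismatch,
        "n_allele_incompatible": n_incompatible,
    }
    return aligned, report


def compute_prs(
    dosages: pd.DataFrame,
    aligned: pd.DataFrame,
    missing_policy: str = "mean_impute",
    eaf: pd.Series | None = None,
) -> pd.Series:
    """Raw PRS per sample: the weighted sum of aligned effect dosages.

    Missing dosages are imputed at twice the effect-allele frequency
    (``missing_policy="mean_impute"``, the score-file tooling convention) or
    skipped for that sample (``"drop"``, no renormalisation).  ``eaf``
    supplies per-variant effect-allele frequencies (e.g. from a reference
    cohort); when absent they are estimated from ``dosages`` itself.
    Samples missing every variant get a missing score.
    """
    if missing_policy not in ("mean_impute", "drop"):
        raise ValueError("missing_policy must be 'mean_impute' or 'drop'")
    ids = aligned["variant_id"].tolist()
    d = dosages[ids].to_numpy(dtype=float)
    flip = aligned["flip"].to_numpy(dtype=bool)
    d = np.where(flip[None, :], 2.0 - d, d)
    w = aligned["weight"].to_numpy(dtype=float)

    all_missing = np.isnan(d).all(axis=1) if d.shape[1] else np.ones(len(dosages), bool)
    if eaf is not None:
        eaf = pd.Series(eaf).reindex(ids).to_numpy(dtype=float)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            eaf = np.nanmean(d, axis=0) / 2.0
    if missing_policy == "mean_impute":
        fill = 2.0 * np.where(np.isfinite(eaf), eaf, 0.0)
        d = np.where(np.isnan(d), fill[None, :], d)
        score = d @ w
    else:
        score = np.nansum(d * w[None, :], axis=1)
    score = np.where(all_missing, np.nan, score)
    return pd.Series(score, index=dosages.index, name="raw_score")


def standardize_and_group(raw_scores: pd.Series) -> pd.DataFrame:
    """Z-standardise raw scores and assign quintile risk groups.

    Z-scores have cohort mean 0 and SD 1.  Risk groups are cut by rank so
    exact 20/60/20 splits hold under ties: the lowest ``round(0.2 n)``
    scores are "low", the highest ``round(0.2 n)`` are "high", the rest
    "middle"; ties are broken by stable input order.
    """
    scores = pd.Series(raw_scores).astype(float)
    valid = scores.dropna()
    if len(valid) < 5:
        raise ValueError("need at least 5 non-missing scores")
    sd = valid.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance in raw scores; cannot standardise")
    z = (scores - valid.mean()) / sd

    n = len(valid)
    k = int(round(0.2 * n))
    order = np.argsort(valid.to_numpy(), kind="stable")
    group = np.full(n, "middle", dtype=object)
    group[order[:k]] = "low"
    if k:
        group[order[n - k:]] = "high"
    groups = pd.Series(pd.NA, index=scores.index, dtype=object)
    groups.loc[valid.index] = group
    return pd.DataFrame(
        {
            "sample_id": scores.index,
            "raw_score": scores.to_numpy(),
            "z_score": z.to_numpy(),
            "risk_group": groups.to_numpy(),
        }
    )


class PRSScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style PRS transformer: QC, alignment, scoring, grouping.

    Parameters
    ----------
    score_variants : validated score-file DataFrame (see
        :func:`read_score_file`).
    call_rate_min, hwe_p_min, r2_min : variant QC thresholds.
    missing_policy : how missing dosages enter the weighted sum.

    ``fit`` expects the dosage matrix (samples x variants, counted-allele
    dosages in [0, 2]) and, through ``dosage_meta``, the counted/uncounted
    alleles plus imputation r2.  Fitted attributes: ``meta_`` (QC table),
    ``qc_report_``, ``aligned_``, ``alignment_report_``, ``mean_``, ``sd_``,
    ``low_cut_``, ``high_cut_``.  ``transform`` returns the per-sample PRS
    table; on the training cohort the risk groups follow the exact rank
    rule, on new samples the stored score cut-points.
    """

    def __init__(
        self,
        score_variants: pd.DataFrame = None,
        call_rate_min: float = 0.90,
        hwe_p_min: float = 1e-6,
        r2_min: float = 0.30,
        missing_policy: str = "mean_impute",
    ):
        self.score_variants = score_variants
        self.call_rate_min = call_rate_min
        self.hwe_p_min = hwe_p_min
        self.r2_min = r2_min
        self.missing_policy = missing_policy

    def fit(self, X: pd.DataFrame, y=None, dosage_meta: pd.DataFrame | None = None):
        if self.score_variants is None:
            raise ValueError("score_variants is required")
        if dosage_meta is None:
            raise ValueError("dosage_meta is required to fit the scorer")
        r2 = (
            dosage_meta.set_index("variant_id")["imputation_r2"]
            if "imputation_r2" in dosage_meta.columns
            else None
        )
        meta = build_variant_meta(X, imputation_r2=r2)
        meta, self.qc_report_ = variant_qc(
            meta, self.call_rate_min, self.hwe_p_min, self.r2_min
        )
        self.meta_ = meta
        passing = set(meta.loc[meta["qc_pass"], "variant_id"])
        score_pass = self.score_variants[self.score_variants["variant_id"].isin(passing)]
        self.aligned_, self.alignment_report_ = align_alleles(score_pass, dosage_meta)
        if self.aligned_.empty:
            raise ValueError("no variant survived QC and allele alignment")

        ids = self.aligned_["variant_id"].tolist()
        d = X[ids].to_numpy(dtype=float)
        d = np.where(self.aligned_["flip"].to_numpy(bool)[None, :], 2.0 - d, d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.eaf_ = pd.Series(np.nanmean(d, axis=0) / 2.0, index=ids)
        raw = compute_prs(X, self.aligned_, self.missing_policy, eaf=self.eaf_)
        table = standardize_and_group(raw)
        valid = raw.dropna()
        self.mean_ = float(valid.mean())
        self.sd_ = float(valid.std(ddof=0))
        grouped = table.set_index("sample_id").loc[valid.index]
        self.low_cut_ = float(valid[grouped["risk_group"] == "low"].max()) if (grouped["risk_group"] == "low").any() else -np.inf
        self.high_cut_ = float(valid[grouped["risk_group"] == "high"].min()) if (grouped["risk_group"] == "high").any() else np.inf
        self._fit_index = X.index
        self._fit_table = table
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "aligned_"):
            raise RuntimeError("PRSScorer must be fitted before transform")
        if X.index.equals(self._fit_index):
            return self._fit_table.copy()
        raw = compute_prs(X, self.aligned_, self.missing_policy, eaf=self.eaf_)
        z = (raw - self.mean_) / self.sd_
        group = np.where(
            raw <= self.low_cut_, "low", np.where(raw >= self.high_cut_, "high", "middle")
        )
        group = pd.Series(group, index=raw.index, dtype=object).where(raw.notna(), pd.NA)
        return pd.DataFrame(
            {
                "sample_id": raw.index,
                "raw_score": raw.to_numpy(),
                "z_score": z.to_numpy(),
                "risk_group": group.to_numpy(),
            }
        )
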