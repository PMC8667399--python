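"""Mosaic loss-of-Y calling from array Log R Ratio (LRR) intensities.

A man's level of Y mosaicism is summarised by mLRRY, the median LRR over the
male-specific-region (MSY) probes of chromosome Y.  mLRRY sits near zero in
unaffected men and moves negative as the fraction of cells lacking the Y
grows.  Calling proceeds in three steps:

1. ``compute_mlrry`` — per-sample median over MSY probes;
2. ``estimate_threshold`` — a lower percentile (default 0.5th) of a
   symmetric experimental-error null built by reflecting the observations
   above the distribution mode; a fixed threshold (e.g. -0.06) can be used
   instead;
3. ``call_loy`` — a strict-inequality binary call plus a continuous
   estimate: the percentage of cells with LOY via
   ``f = 1 - 2**(mLRRY / c)`` with array response factor ``c`` (default
   0.46, which maps mLRRY = -0.06 to 8.6% of cells).

:class:`LOYCaller` wraps the three steps as a scikit-learn style estimator
(samples as rows, probes as columns).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdEstimate",
    "LOYCaller",
    "compute_mlrry",
    "estimate_threshold",
    "mlrry_to_fraction",
    "call_loy",
    "prevalence_by_age",
]

DEFAULT_RESPONSE_FACTOR = 0.46
DEFAULT_PERCENTILE = 0.005


@dataclass(frozen=True)
class ThresholdEstimate:
    """An LOY calling threshold with the null model it came from."""

    mode: float
    threshold: float
    percentile: float
    method: str  # "reflected_null" or "fixed"

    def __post_init__(self) -> None:
        if self.method == "reflected_null" and not 0 < self.percentile < 0.5:
            raise ValueError("percentile must be in (0, 0.5)")
        if self.threshold > self.mode + 1e-12:
            raise ValueError("threshold must not exceed the null mode")


def compute_mlrry(lrr: pd.DataFrame, probe_annotation: pd.DataFrame) -> pd.DataFrame:
    """Median LRR over MSY probes, per sample.

    Parameters
    ----------
    lrr : DataFrame, probes x samples, indexed by probe_id.
    probe_annotation : DataFrame with ``probe_id`` and ``is_msy`` columns.

    Returns a DataFrame (sample_id, mlrry, n_probes_used).  Samples with no
    usable MSY probe get NaN and are logged; missing probe values are
    ignored by the median.
    """
    msy_ids = probe_annotation.loc[probe_annotation["is_msy"].astype(bool), "probe_id"]
    msy_ids = msy_ids[msy_ids.isin(lrr.index)]
    if len(msy_ids) == 0:
        raise ValueError("no MSY-flagged probe present in the LRR matrix")
    sub = lrr.loc[msy_ids]
    n_used = sub.notna().sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(sub.to_numpy(dtype=float), axis=0)
    med = np.where(n_used.to_numpy() > 0, med, np.nan)
    n_unscorable = int((n_used == 0).sum())
    if n_unscorable:
        logger.warning("%d sample(s) had zero usable MSY probes and are unscorable", n_unscorable)
    return pd.DataFrame(
        {"sample_id": lrr.columns, "mlrry": med, "n_probes_used": n_used.to_numpy()}
    )


def estimate_threshold(
    mlrry_values, percentile: float = DEFAULT_PERCENTILE
) -> ThresholdEstimate:
    """Calling threshold from a reflected experimental-error null.

    The mode of the mLRRY distribution (the unaffected peak near zero) is
    located by kernel density estimation; deviations of the observations at
    or above the mode define a symmetric technical-noise null, and the
    threshold is that null's lower ``percentile`` quantile:
    ``mode - q_{1 - 2*percentile}(deviations)``.  For pure Gaussian noise of
    spread sigma and percentile 0.005 this converges to ``mode - 2.576*sigma``.
    """
    if not 0 < percentile < 0.5:
        raise ValueError("percentile must be in (0, 0.5)")
    x = np.asarray(mlrry_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite mLRRY values")
    if x.size < 100:
        warnings.warn(
            f"threshold estimated from only {x.size} samples; >= 100 recommended",
            RuntimeWarning,
        )
    if np.ptp(x) == 0:
        warnings.warn("degenerate mLRRY distribution (all values identical)", RuntimeWarning)
        v = float(x[0])
        return ThresholdEstimate(mode=v, threshold=v, percentile=percentile, method="reflected_null")

    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 4096)
    mode = float(grid[np.argmax(kde(grid))])

    deviations = x[x >= mode] - mode
    # the (1 - 2p) quantile of the one-sided deviations equals the (1 - p)
    # quantile of the symmetrised null
    q = float(np.quantile(deviations, 1.0 - 2.0 * percentile))
    return ThresholdEstimate(
        mode=mode, threshold=mode - q, percentile=percentile, method="reflected_null"
    )


def mlrry_to_fraction(mlrry, response_factor: float = DEFAULT_RESPONSE_FACTOR):
    """Percentage of cells with LOY implied by mLRRY.

    Uses ``f = 1 - 2**(mLRRY / c)`` clamped to [0, 1] and reported in
    percent; positive mLRRY maps to 0.  With the default c = 0.46,
    mLRRY = -0.06 gives 8.6% of cells.
    """
    if not 0 < response_factor <= 1:
        raise ValueError("response_factor must be in (0, 1]")
    m = np.asarray(mlrry, dtype=float)
    frac = 1.0 - np.exp2(m / response_factor)
    pct = 100.0 * np.clip(frac, 0.0, 1.0)
    if np.isscalar(mlrry) or np.ndim(mlrry) == 0:
        return float(pct)
    return pct


def call_loy(
    mlrry_results: pd.DataFrame,
    threshold: float | ThresholdEstimate,
    response_factor: float = DEFAULT_RESPONSE_FACTOR,
) -> pd.DataFrame:
    """Binary and continuous LOY variables per sample.

    A sample is called LOY iff its mLRRY is strictly below the threshold.
    Unscorable samples (NaN mLRRY) propagate as missing calls.
    """
    thr = threshold.threshold if isinstance(threshold, ThresholdEstimate) else float(threshold)
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    m = mlrry_results["mlrry"].to_numpy(dtype=float)
    is_loy = pd.array(m < thr, dtype="boolean")
    is_loy[np.isnan(m)] = pd.NA
    out = pd.DataFrame(
        {
            "sample_id": mlrry_results["sample_id"].to_numpy(),
            "mlrry": m,
            "n_probes_used": mlrry_results["n_probes_used"].to_numpy(),
            "fraction_pct": mlrry_to_fraction(m, response_factor),
            "is_loy": is_loy,
            "threshold_used": thr,
        }
    )
    return out


def prevalence_by_age(
    calls: pd.DataFrame,
    covariates: pd.DataFrame,
    bin_edges: tuple[float, ...] = (70.0, 75.0, 80.0, 85.0),
) -> pd.DataFrame:
    """LOY counts and percentages per age bin.

    Bins are left-closed, right-open; the last bin is unbounded above.
    Empty bins report a missing percentage rather than 0.
    """
    merged = calls.merge(covariates[["sample_id", "age"]], on="sample_id")
    edges = list(bin_edges) + [np.inf]
    labels = [
        f"{int(edges[i])}-{int(edges[i + 1]) - 1}" if np.isfinite(edges[i + 1]) else f"{int(edges[i])}+"
        for i in range(len(bin_edges))
    ]
    idx = np.digitize(merged["age"].to_numpy(dtype=float), bin_edges) - 1
    rows = []
    for b, label in enumerate(labels):
        in_bin = merged[idx == b]
        scored = in_bin[in_bin["is_loy"].notna()]
        n = len(scored)
        n_loy = int(scored["is_loy"].sum()) if n else 0
        rows.append(
            {
                "age_bin": label,
                "n": n,
                "n_loy": n_loy,
                "pct_loy": 100.0 * n_loy / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


class LOYCaller(BaseEstimator, TransformerMixin):
    """Scikit-learn style LOY caller over an LRR matrix (samples x probes).

    Parameters
    ----------
    msy_probes : sequence of column names flagged as MSY, or None to use
        every column.
    threshold : "reflected_null" to estimate the calling threshold from the
        cohort's experimental-error null, or a fixed LRR value such as
        -0.06 to replicate a published operating point.
    percentile : lower tail probability of the null used for the estimated
        threshold.
    response_factor : array response factor c of the mLRRY-to-fraction map.

    Attributes (after ``fit``)
    --------------------------
    threshold_ : float — the calling threshold in LRR units.
    threshold_estimate_ : ThresholdEstimate — null metadata.
    mlrry_ : Series — training-cohort mLRRY values.
    """

    def __init__(
        self,
        msy_probes=None,
        threshold="reflected_null",
        percentile: float = DEFAULT_PERCENTILE,
        response_factor: float = DEFAULT_RESPONSE_FACTOR,
    ):
        self.msy_probes = msy_probes
        self.threshold = threshold
        self.percentile = percentile
        self.response_factor = response_factor

    def _mlrry(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        cols = list(self.msy_probes) if self.msy_probes is not None else list(X.columns)
        annotation = pd.DataFrame({"probe_id": cols, "is_msy": 1})
        return compute_mlrry(X[cols].T, annotation)

    def fit(self, X, y=None):
        mlrry = self._mlrry(X)
        self.mlrry_ = pd.Series(
            mlrry["mlrry"].to_numpy(), index=mlrry["sample_id"].to_numpy(), name="mlrry"
        )
        if self.threshold == "reflected_null":
            self.threshold_estimate_ = estimate_threshold(self.mlrry_, self.percentile)
        else:
            thr = float(self.threshold)
            self.threshold_estimate_ = ThresholdEstimate(
                mode=max(0.0, thr), threshold=thr, percentile=self.percentile, method="fixed"
            )
        self.threshold_ = self.threshold_estimate_.threshold
        return self

    def transform(self, X) -> pd.DataFrame:
        """Per-sample call table (mlrry, fraction_pct, is_loy, ...)."""
        if not hasattr(self, "threshold_"):
            raise RuntimeError("LOYCaller must be fitted before transform")
        return call_loy(self._mlrry(X), self.threshold_estimate_, self.response_factor)

    def predict(self, X) -> np.ndarray:
        """Binary LOY calls (NaN-safe boolean array with pd.NA for unscorable)."""
        return self.transform(X)["is_loy"].to_numpy()
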