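"""LOY estimation from whole-genome-sequencing read depth.

In an unaffected diploid male, coverage over the male-specific region of
chromosome Y (MSY) is half the autosomal coverage (one Y per genome).  With
a mosaic fraction ``f`` of cells lacking the Y, expected MSY depth falls to
``autosomal_depth * (1 - f) / 2``, so

    y_log2_ratio = log2( mean(MSY counts) / (0.5 * mean(autosomal counts)) )
    fraction_pct = 100 * (1 - 2**y_log2_ratio), clamped to [0, 100].

Segmentation and GC correction belong to upstream copy-number tooling;
this module consumes precomputed per-window read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = ["ConcordanceResult", "depth_log_ratio", "concordance"]


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson concordance between paired array and WGS LOY estimates."""

    r: float
    n: int
    n_excluded: int


def depth_log_ratio(windows: pd.DataFrame, agg: str = "mean") -> pd.DataFrame:
    """Per-sample MSY/autosome depth log2 ratio and implied cell fraction.

    Parameters
    ----------
    windows : long table with columns sample_id, region_class
        ("MSY"/"autosomal") and read_count.
    agg : "mean" (default; Poisson windows are outlier-free) or "median"
        (preferable on real data with coverage artefacts).

    Samples lacking an MSY or autosomal window, or with zero total
    autosomal coverage, are unscorable (NaN) and logged.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    if (windows["read_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    fn = np.mean if agg == "mean" else np.median
    rows = []
    n_unscorable = 0
    for sid, grp in windows.groupby("sample_id", sort=False):
        msy = grp.loc[grp["region_class"] == "MSY", "read_count"].to_numpy(dtype=float)
        auto = grp.loc[grp["region_class"] == "autosomal", "read_count"].to_numpy(dtype=float)
        if msy.size == 0 or auto.size == 0 or auto.sum() == 0 or fn(auto) == 0:
            rows.append({"sample_id": sid, "y_log2_ratio": np.nan, "fraction_pct": np.nan})
            n_unscorable += 1
            continue
        ratio = fn(msy) / (0.5 * fn(auto))
        y = np.log2(ratio) if ratio > 0 else -np.inf
        frac = 100.0 * float(np.clip(1.0 - 2.0**y, 0.0, 1.0))
        rows.append({"sample_id": sid, "y_log2_ratio": y, "fraction_pct": frac})
    if n_unscorable:
        logger.warning("%d WGS sample(s) unscorable (no usable windows)", n_unscorable)
    return pd.DataFrame(rows, columns=["sample_id", "y_log2_ratio", "fraction_pct"])


def concordance(array_values: pd.Series, wgs_values: pd.Series) -> ConcordanceResult:
    """Pearson correlation between array- and WGS-derived LOY estimates.

    Values are paired on their index (sample id); samples missing on either
    side are excluded and counted.  Fewer than 3 complete pairs, or zero
    variance on either side, raise ``ValueError``.
    """
    a = pd.Series(array_values).astype(float)
    b = pd.Series(wgs_values).astype(float)
    common = a.index.intersection(b.index)
    paired = pd.DataFrame({"a": a.loc[common], "b": b.loc[common]}).dropna()
    n_excluded = len(a.index.union(b.index)) - len(paired)
    if len(paired) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(paired)}")
    if paired["a"].std(ddof=0) == 0 or paired["b"].std(ddof=0) == 0:
        raise ValueError("zero variance on one side; correlation undefined")
    r = float(pearsonr(paired["a"], paired["b"]).statistic)
    return ConcordanceResult(r=r, n=len(paired), n_excluded=n_excluded)
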