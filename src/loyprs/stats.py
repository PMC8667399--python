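"""Association and prediction statistics for the LOY analysis.

Covers the inferential toolkit of the analysis: baseline-table tests
(Welch t, Pearson chi-square), Wilcoxon rank-sum with tie correction,
ANCOVA of the PRS distribution by LOY status, logistic and linear
association models with Wald intervals, quintile and age-stratified odds
ratios, and ROC/AUC with DeLong variance and the paired DeLong test for
correlated AUCs.

Model fitting is delegated to statsmodels (GLM/OLS); the ROC machinery
(midrank AUC, DeLong structural components) is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.stats import norm, rankdata

__all__ = [
    "AssociationResult",
    "AncovaResult",
    "ModelError",
    "ModelSpec",
    "ROCResult",
    "TestResult",
    "age_stratified_association",
    "ancova_prs",
    "baseline_table",
    "chi_square_test",
    "delong_test",
    "fit_linear",
    "fit_logistic",
    "risk_group_design",
    "roc_auc",
    "t_test",
    "wilcoxon_rank_sum",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ModelError(RuntimeError):
    """Model could not be fitted (rank deficiency, separation, divergence)."""


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


@dataclass
class ModelSpec:
    """Declarative description of an association model."""

    outcome: str  # "loy_binary", "mlrry_continuous" or "prs"
    predictors: tuple[str, ...]
    strata: tuple[float, float] | None = None  # optional [low, high) age filter


@dataclass
class AssociationResult:
    """Fitted model: per-term coefficients, Wald intervals and p-values.

    ``table`` is indexed by term with columns coef, se, ci_low, ci_high, p
    and, for binary outcomes, odds_ratio, or_ci_low, or_ci_high.
    """

    model: str
    n: int
    converged: bool
    n_iter: int
    table: pd.DataFrame

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "odds_ratio"])


@dataclass
class AncovaResult:
    pvalue: float
    adjusted_means: dict
    fit: AssociationResult


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    var: float
    n_pos: int
    n_neg: int


def _check_design(X: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if X.isna().any().any():
        raise ModelError("design matrix contains missing values")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending columns via incremental rank
        collinear = []
        cols = list(Xc.columns)
        for j in range(1, len(cols) + 1):
            if np.linalg.matrix_rank(Xc.iloc[:, :j].to_numpy()) < j:
                collinear.append(cols[j - 1])
        raise ModelError(f"design matrix is rank deficient; collinear term(s): {collinear}")
    return Xc


def fit_logistic(y, X: pd.DataFrame, maxiter: int = 25, tol: float = 1e-8) -> AssociationResult:
    """Logistic regression by IRLS with Wald 95% intervals.

    ``y`` is a binary outcome, ``X`` a DataFrame of predictors (an intercept
    is added).  Odds ratios are ``exp(coef)`` with CI
    ``exp(coef +/- 1.96 se)``.  Separation or non-convergence raises
    :class:`ModelError` with diagnostics.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y[~np.isnan(y)], (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    Xc = _check_design(X)
    if np.isnan(y).any():
        raise ModelError("outcome contains missing values")
    try:
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
        raise ModelError(f"logistic fit failed: {exc}") from exc
    coefs = res.params
    if not res.converged:
        raise ModelError(
            f"logistic fit did not converge in {maxiter} IRLS iterations "
            f"(max |coef| = {np.abs(coefs).max():.3g})"
        )
    if np.abs(coefs.drop("const")).max() > 15:
        raise ModelError(
            "apparent separation: a coefficient exceeds 15 on the log-odds scale "
            f"({coefs.drop('const').abs().idxmax()})"
        )
    se = res.bse
    table = pd.DataFrame(
        {
            "coef": coefs,
            "se": se,
            "ci_low": coefs - Z95 * se,
            "ci_high": coefs + Z95 * se,
            "p": res.pvalues,
            "odds_ratio": np.exp(coefs),
            "or_ci_low": np.exp(coefs - Z95 * se),
            "or_ci_high": np.exp(coefs + Z95 * se),
        }
    )
    history = getattr(res, "fit_history", None) or {}
    n_iter = len(history.get("deviance", [])) or maxiter
    return AssociationResult(
        model="logistic", n=len(y), converged=bool(res.converged), n_iter=int(n_iter), table=table
    )


def fit_linear(y, X: pd.DataFrame) -> AssociationResult:
    """Ordinary least squares with t-based p-values and 95% intervals."""
    y = np.asarray(y, dtype=float)
    Xc = _check_design(X)
    if np.isnan(y).any():
        raise ModelError("outcome contains missing values")
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )
    return AssociationResult(model="linear", n=len(y), converged=True, n_iter=0, table=table)


def ancova_prs(prs_z, loy_binary, covariates: pd.DataFrame) -> AncovaResult:
    """Compare mean PRS between LOY groups adjusting for covariates.

    Fits ``prs_z ~ loy + covariates`` by OLS; the reported p-value is the
    LOY term's, and the adjusted group means are evaluated at the covariate
    means.
    """
    X = pd.DataFrame(covariates).copy()
    X.insert(0, "loy", np.asarray(loy_binary, dtype=float))
    fit = fit_linear(prs_z, X)
    cov_means = X.drop(columns="loy").mean()
    base = float(fit.table.loc["const", "coef"] + (fit.table["coef"].reindex(cov_means.index) * cov_means).sum())
    means = {"no_loy": base, "loy": base + float(fit.table.loc["loy", "coef"])}
    return AncovaResult(pvalue=float(fit.table.loc["loy", "p"]), adjusted_means=means, fit=fit)


def t_test(group_a, group_b) -> TestResult:
    """Welch two-sample t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0)
        return TestResult(np.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(t), float(p))


def wilcoxon_rank_sum(group_a, group_b) -> TestResult:
    """Wilcoxon rank-sum test, normal approximation with tie correction.

    The statistic is the rank sum of ``group_a`` in the pooled sample.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(w, 1.0)
    z = (w - mu) / np.sqrt(var)
    return TestResult(w, float(2.0 * norm.sf(abs(z))))


def chi_square_test(contingency) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, df, p).  A zero row or column margin raises
    ``ValueError``.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def baseline_table(covariates: pd.DataFrame, loy_binary) -> pd.DataFrame:
    """Cohort characteristics by LOY status with the usual tests.

    Age: mean (SD) per column with a Welch t-test.  Categorical variables
    (smoking, alcohol, treatment, BMI category): counts and one-decimal
    column percentages with a chi-square test; empty categories are kept
    with count 0 and excluded from the test only if their margin is zero.
    """
    loy = np.asarray(loy_binary, dtype=float)
    df = covariates.reset_index(drop=True)
    is_loy = loy == 1
    rows = []

    age = df["age"].to_numpy(dtype=float)
    t_p = t_test(age[~is_loy], age[is_loy]).pvalue
    rows.append(
        {
            "variable": "age",
            "level": "mean_sd",
            "all": f"{age.mean():.1f} ({age.std(ddof=1):.2f})",
            "loy_no": f"{age[~is_loy].mean():.1f} ({age[~is_loy].std(ddof=1):.2f})",
            "loy_yes": f"{age[is_loy].mean():.1f} ({age[is_loy].std(ddof=1):.2f})",
            "p": t_p,
        }
    )

    categorical = {
        "smoking": ["never", "former", "current"],
        "alcohol": ["never", "former", "current"],
        "treatment": ["placebo", "aspirin"],
        "bmi_category": ["underweight", "normal", "overweight", "obese", "missing"],
    }
    for var, levels in categorical.items():
        if var not in df.columns:
            continue
        present = [lv for lv in levels if lv in set(df[var])] or levels
        counts = np.array(
            [
                [int(((df[var] == lv) & ~is_loy).sum()), int(((df[var] == lv) & is_loy).sum())]
                for lv in present
            ]
        )
        nonzero = counts.sum(axis=1) > 0
        if nonzero.sum() >= 2 and (counts[nonzero].sum(axis=0) > 0).all():
            _, _, chi_p = chi_square_test(counts[nonzero])
        else:
            chi_p = np.nan
        for k, lv in enumerate(levels):
            n_no = int(((df[var] == lv) & ~is_loy).sum())
            n_yes = int(((df[var] == lv) & is_loy).sum())
            n_all = n_no + n_yes
            rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "all": f"{n_all} ({100 * n_all / len(df):.1f}%)" if len(df) else "0",
                    "loy_no": f"{n_no} ({100 * n_no / max(1, (~is_loy).sum()):.1f}%)",
                    "loy_yes": f"{n_yes} ({100 * n_yes / max(1, is_loy.sum()):.1f}%)",
                    "p": chi_p if k == 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _roc_components(scores: np.ndarray, labels: np.ndarray):
    """Midrank AUC and DeLong structural components (per-positive, per-negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (tz[:m] - tx) / n  # P(score_neg < pos_i), midrank convention
    v_neg = 1.0 - (tz[m:] - ty) / m
    return float(auc), v_pos, v_neg


def roc_auc(predicted, labels) -> ROCResult:
    """AUC via the Mann-Whitney rank identity with a DeLong 95% CI."""
    scores = np.asarray(predicted, dtype=float)
    y = np.asarray(labels, dtype=float)
    auc, v_pos, v_neg = _roc_components(scores, y)
    m, n = len(v_pos), len(v_neg)
    s10 = v_pos.var(ddof=1) if m > 1 else 0.0
    s01 = v_neg.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = Z95 * np.sqrt(var)
    return ROCResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        var=float(var),
        n_pos=m,
        n_neg=n,
    )


def delong_test(pred_model1, pred_model2, labels) -> TestResult:
    """Paired DeLong test for two correlated AUCs on the same samples.

    Returns (z, two-sided p).  Identical prediction vectors give z = 0,
    p = 1.
    """
    s1 = np.asarray(pred_model1, dtype=float)
    s2 = np.asarray(pred_model2, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s1.shape != s2.shape or s1.shape != y.shape:
        raise ValueError("predictions and labels must be aligned on the same samples")
    auc1, v1p, v1n = _roc_components(s1, y)
    auc2, v2p, v2n = _roc_components(s2, y)
    m, n = len(v1p), len(v1n)
    sx = np.cov(np.vstack([v1p, v2p]), ddof=1) if m > 1 else np.zeros((2, 2))
    sy = np.cov(np.vstack([v1n, v2n]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = sx / m + sy / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-300:
        return TestResult(0.0, 1.0)
    z = (auc1 - auc2) / np.sqrt(var_diff)
    return TestResult(float(z), float(2.0 * norm.sf(abs(z))))


def risk_group_design(risk_group: pd.Series, reference: str = "low") -> pd.DataFrame:
    """Indicator columns for PRS risk groups against a reference level."""
    groups = pd.Series(risk_group).astype(object)
    levels = [g for g in ("low", "middle", "high") if g != reference]
    if not set(groups.dropna()) <= {"low", "middle", "high"}:
        raise ValueError("risk groups must be low/middle/high")
    return pd.DataFrame(
        {f"prs_{lv}": (groups == lv).astype(float).to_numpy() for lv in levels},
        index=groups.index,
    )


def age_stratified_association(
    covariates: pd.DataFrame,
    prs_groups: pd.Series,
    loy_binary,
    bins: tuple[tuple[float, float], ...] = ((70.0, 75.0), (75.0, 80.0), (80.0, np.inf)),
) -> dict:
    """Per-age-bin logistic fits of LOY on PRS group, smoking and alcohol.

    Age bins are left-closed, right-open (age 75.0 belongs to 75-79, 80.0
    to 80+); age itself is excluded within strata.  Bins where the model is
    not estimable (a single outcome class or fewer than two PRS groups) are
    reported with a reason rather than dropped.
    """
    loy = np.asarray(loy_binary, dtype=float)
    groups = pd.Series(prs_groups).reset_index(drop=True)
    df = covariates.reset_index(drop=True)
    out = {}
    for lo, hi in bins:
        label = f"{int(lo)}-{int(hi) - 1}" if np.isfinite(hi) else f"{int(lo)}+"
        mask = (df["age"].to_numpy(dtype=float) >= lo) & (df["age"].to_numpy(dtype=float) < hi)
        y = loy[mask]
        g = groups[mask]
        if len(y) == 0 or len(np.unique(y)) < 2 or g.dropna().nunique() < 2:
            out[label] = {"estimable": False, "reason": "needs both outcomes and >= 2 PRS groups", "n": int(mask.sum())}
            continue
        X = risk_group_design(g.reset_index(drop=True))
        X["smoking_current"] = (df.loc[mask, "smoking"] == "current").astype(float).to_numpy()
        X["alcohol_current"] = (df.loc[mask, "alcohol"] == "current").astype(float).to_numpy()
        try:
            out[label] = fit_logistic(y, X)
        except ModelError as exc:
            out[label] = {"estimable": False, "reason": str(exc), "n": int(mask.sum())}
    return out
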