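"""Inferential machinery: model fits, baseline tests, ROC/AUC, DeLong."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from loyprs.stats import (
    ModelError,
    age_stratified_association,
    ancova_prs,
    baseline_table,
    chi_square_test,
    delong_test,
    fit_linear,
    fit_logistic,
    risk_group_design,
    roc_auc,
    t_test,
    wilcoxon_rank_sum,
)


def _two_by_two(a, b, c, d):
    """Outcome/exposure data with cell counts a=y1x1, b=y1x0, c=y0x1, d=y0x0."""
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, pd.DataFrame({"x": x})


class TestFitLogistic:
    @pytest.mark.parametrize("cells", [(20, 30, 10, 40), (55, 13, 21, 34), (8, 9, 10, 11)])
    def test_two_by_two_matches_cross_product_ratio(self, cells):
        a, b, c, d = cells
        y, X = _two_by_two(a, b, c, d)
        fit = fit_logistic(y, X)
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(a * d / (b * c), rel=1e-6)
        assert fit.table.loc["x", "se"] == pytest.approx(
            math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-6
        )

    def test_null_simulation_covers_one(self):
        """With no true effect the OR is near 1 and the CI usually covers it."""
        rng = np.random.default_rng(23)
        covered = 0
        for _ in range(40):
            X = pd.DataFrame({"x": rng.normal(size=400)})
            y = rng.integers(0, 2, size=400).astype(float)
            t = fit_logistic(y, X).table
            covered += t.loc["x", "or_ci_low"] <= 1 <= t.loc["x", "or_ci_high"]
        assert covered >= 33  # ~95% nominal coverage

    def test_separation_raises(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        X = pd.DataFrame({"x": np.concatenate([np.zeros(20), np.ones(20)])})
        with pytest.raises(ModelError):
            fit_logistic(y, X)

    def test_rank_deficiency_names_term(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ModelError, match="x2"):
            fit_logistic(y, X)

    def test_outcome_must_be_binary(self):
        with pytest.raises(ValueError):
            fit_logistic(np.array([0.0, 0.5, 1.0]), pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


class TestFitLinear:
    def test_exact_linear_function_recovered(self):
        x = np.linspace(0, 1, 30)
        X = pd.DataFrame({"x": x})
        fit = fit_linear(3.0 * x + 1.5, X)
        assert fit.table.loc["x", "coef"] == pytest.approx(3.0, abs=1e-10)
        assert fit.table.loc["const", "coef"] == pytest.approx(1.5, abs=1e-10)

    def test_intercept_only_gives_sample_mean(self):
        y = np.array([2.0, 4.0, 9.0])
        fit = fit_linear(y, pd.DataFrame(index=range(3)))
        assert fit.table.loc["const", "coef"] == pytest.approx(y.mean())

    def test_orthogonal_predictors_equal_univariate_slopes(self):
        rng = np.random.default_rng(2)
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 -= x2.mean()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalise
        y = rng.normal(size=n)
        joint = fit_linear(y, pd.DataFrame({"x1": x1, "x2": x2})).table
        for name, x in (("x1", x1), ("x2", x2)):
            solo = fit_linear(y, pd.DataFrame({name: x})).table
            assert joint.loc[name, "coef"] == pytest.approx(solo.loc[name, "coef"], abs=1e-10)


class TestAncova:
    def test_reduces_to_pooled_t_test_without_covariates(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=120)
        loy = rng.integers(0, 2, size=120)
        res = ancova_prs(z, loy, pd.DataFrame(index=range(120)))
        t_p = sps.ttest_ind(z[loy == 0], z[loy == 1], equal_var=True).pvalue
        assert res.pvalue == pytest.approx(t_p, abs=1e-9)

    def test_shifted_prs_detected(self):
        rng = np.random.default_rng(4)
        n = 5000
        loy = rng.integers(0, 2, size=n)
        z = rng.normal(size=n) + 0.5 * loy
        cov = pd.DataFrame({"age": rng.uniform(70, 90, size=n)})
        res = ancova_prs(z, loy, cov)
        assert res.pvalue < 1e-3
        assert res.adjusted_means["loy"] - res.adjusted_means["no_loy"] == pytest.approx(0.5, abs=0.1)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            z = rng.normal(size=80)
            loy = rng.integers(0, 2, size=80)
            cov = pd.DataFrame({"age": rng.uniform(70, 90, size=80)})
            pvals.append(ancova_prs(z, loy, cov).pvalue)
        assert 0.2 * 0.5 < np.mean(np.array(pvals) < 0.5) < 1.8 * 0.5


class TestSimpleTests:
    def test_welch_identical_groups(self):
        assert t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).pvalue == pytest.approx(1.0)

    def test_constant_equal_groups_p_one(self):
        assert t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(6)
        assert t_test(rng.normal(0, 1, 500), rng.normal(2, 1, 500)).pvalue < 1e-3
        assert wilcoxon_rank_sum(rng.normal(0, 1, 500), rng.normal(2, 1, 500)).pvalue < 1e-3

    def test_wilcoxon_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0]).pvalue == 1.0

    def test_wilcoxon_against_exhaustive_permutation(self):
        """Normal-approximation p tracks the exact permutation p at n <= 8."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(size=7)
            b = rng.normal(0.8, 1.0, size=6)
            stat, p = wilcoxon_rank_sum(a, b)
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            mu = len(a) * (len(pooled) + 1) / 2.0
            obs_dev = abs(stat - mu)
            count = total = 0
            for combo in itertools.combinations(range(len(pooled)), len(a)):
                w = ranks[list(combo)].sum()
                count += abs(w - mu) >= obs_dev - 1e-12
                total += 1
            exact = count / total
            assert abs(p - exact) < 0.05

    def test_chi_square_independent_uniform_table(self):
        stat, df, p = chi_square_test([[25, 25], [25, 25]])
        assert stat == pytest.approx(0.0)
        assert df == 1 and p == pytest.approx(1.0)

    def test_chi_square_smoking_by_loy_significant(self):
        # never/former/current by LOY status in a 5131-man cohort
        table = [[1680, 573], [1952, 747], [107, 72]]
        stat, df, p = chi_square_test(table)
        assert df == 2
        assert p < 0.001

    def test_chi_square_matches_expected_count_formula(self):
        rng = np.random.default_rng(8)
        obs = rng.integers(5, 60, size=(2, 2)).astype(float)
        stat, df, p = chi_square_test(obs)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_chi_square_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test([[0, 0], [5, 5]])


class TestBaselineTable:
    def _cohort(self):
        rng = np.random.default_rng(9)
        n = 400
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age": rng.uniform(70, 90, size=n),
                "smoking": rng.choice(["never", "former", "current"], size=n),
                "alcohol": rng.choice(["never", "former", "current"], size=n),
                "treatment": rng.choice(["placebo", "aspirin"], size=n),
                "bmi_category": rng.choice(["normal", "overweight", "obese"], size=n),
            }
        ), rng.integers(0, 2, size=n)

    def test_percentages_use_column_denominator(self):
        cov, loy = self._cohort()
        out = baseline_table(cov, loy)
        row = out[(out["variable"] == "smoking") & (out["level"] == "never")].iloc[0]
        n_all = int(row["all"].split(" ")[0])
        pct = float(row["all"].split("(")[1].rstrip("%)"))
        assert pct == round(100 * n_all / len(cov), 1)

    def test_empty_category_kept_with_zero(self):
        cov, loy = self._cohort()
        out = baseline_table(cov, loy)
        under = out[(out["variable"] == "bmi_category") & (out["level"] == "underweight")]
        assert len(under) == 1 and under["all"].iloc[0].startswith("0 (")

    def test_identical_groups_chi_square_null(self):
        cov, _ = self._cohort()
        # duplicate the cohort so LOY yes/no have identical category counts
        cov2 = pd.concat([cov, cov], ignore_index=True)
        loy = np.array([0] * len(cov) + [1] * len(cov))
        out = baseline_table(cov2, loy)
        p = out.loc[(out["variable"] == "smoking"), "p"].dropna().iloc[0]
        assert p == pytest.approx(1.0)


class TestROC:
    def test_perfect_separation_auc_one(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(10)
        res = roc_auc(rng.normal(size=4000), rng.integers(0, 2, size=4000))
        assert res.auc == pytest.approx(0.5, abs=0.05)
        assert res.ci_low < 0.5 < res.ci_high

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        scores = np.round(rng.normal(size=n), 1)  # ties on purpose
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, labels).auc == pytest.approx(wins / (len(pos) * len(neg)), rel=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=500)
        labels = (rng.random(500) < sps.norm.cdf(scores)).astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_models_p_one(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        assert delong_test(s, s.copy(), y) == (0.0, 1.0)

    def test_antisymmetric_in_model_order(self):
        rng = np.random.default_rng(13)
        s1, s2 = rng.normal(size=200), rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        z12 = delong_test(s1, s2, y).statistic
        z21 = delong_test(s2, s1, y).statistic
        assert z12 == pytest.approx(-z21)

    def test_type_one_error_calibration_quick(self):
        """Null rejection rate near 5% (a coarser version of the full check)."""
        rng = np.random.default_rng(14)
        rejections = 0
        reps = 400
        for _ in range(reps):
            y = np.concatenate([np.ones(60), np.zeros(60)])
            s1, s2 = rng.normal(size=120), rng.normal(size=120)
            rejections += delong_test(s1, s2, y).pvalue < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_detects_clear_auc_difference(self):
        rng = np.random.default_rng(15)
        n = 2000
        signal = rng.normal(size=n)
        y = (rng.random(n) < sps.norm.cdf(1.5 * signal)).astype(int)
        good = signal + rng.normal(0, 0.5, size=n)
        bad = rng.normal(size=n)
        z, p = delong_test(good, bad, y)
        assert z > 0 and p < 1e-6


class TestAgeStratified:
    def _cohort(self, n=1200, seed=16):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame(
            {
                "age": rng.uniform(70, 90, size=n),
                "smoking": rng.choice(["never", "former", "current"], size=n),
                "alcohol": rng.choice(["never", "former", "current"], size=n),
            }
        )
        groups = pd.Series(rng.choice(["low", "middle", "high"], size=n))
        return cov, groups, rng

    def test_bin_edges_left_closed(self):
        cov, groups, rng = self._cohort()
        cov.loc[0, "age"] = 75.0
        cov.loc[1, "age"] = 80.0
        loy = rng.integers(0, 2, size=len(cov))
        out = age_stratified_association(cov, groups, loy)
        assert set(out) == {"70-74", "75-79", "80+"}
        n_mid = out["75-79"].n if hasattr(out["75-79"], "n") else out["75-79"]["n"]
        assert (cov["age"].between(75, 80, inclusive="left")).sum() == n_mid

    def test_homogeneous_risk_gives_or_near_one(self):
        cov, groups, rng = self._cohort(n=4000, seed=17)
        loy = (rng.random(4000) < 0.3).astype(float)
        out = age_stratified_association(cov, groups, loy)
        for res in out.values():
            assert res.table.loc["prs_high", "or_ci_low"] <= 1.15
            assert res.table.loc["prs_high", "or_ci_high"] >= 0.85

    def test_unestimable_bin_reported_not_dropped(self):
        cov, groups, _ = self._cohort(n=300, seed=18)
        cov["age"] = np.random.default_rng(0).uniform(70, 74, size=300)  # nobody over 75
        loy = np.random.default_rng(1).integers(0, 2, size=300)
        out = age_stratified_association(cov, groups, loy)
        assert out["80+"]["estimable"] is False

    def test_risk_group_design_reference(self):
        X = risk_group_design(pd.Series(["low", "middle", "high", "low"]))
        assert list(X.columns) == ["prs_middle", "prs_high"]
        assert X.to_numpy().tolist() == [[0, 0], [1, 0], [0, 1], [0, 0]]
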