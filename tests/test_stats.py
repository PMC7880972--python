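import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from t1liver.stats import (
    auc_difference,
    delong_compare,
    hosmer_lemeshow,
    icc_two_way_mixed,
    roc_with_youden,
    stepwise_logistic,
    univariate_compare,
    youden_index,
)


# ------------------------------------------------------------------ oracles
def naive_delong(scores_a, scores_b, labels):
    """Independent structural-components implementation (double loops)."""

    def components(s):
        pos = s[labels == 1]
        neg = s[labels == 0]
        m, n = len(pos), len(neg)

        def psi(x, y):
            return 1.0 if x > y else (0.5 if x == y else 0.0)

        v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
        v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
        return v10.mean(), v10, v01

    auc_a, v10_a, v01_a = components(np.asarray(scores_a, float))
    auc_b, v10_b, v01_b = components(np.asarray(scores_b, float))
    m, n = len(v10_a), len(v01_a)

    def cov(u, v):
        return np.sum((u - u.mean()) * (v - v.mean())) / (len(u) - 1)

    var = (
        cov(v10_a, v10_a) + cov(v10_b, v10_b) - 2 * cov(v10_a, v10_b)
    ) / m + (cov(v01_a, v01_a) + cov(v01_b, v01_b) - 2 * cov(v01_a, v01_b)) / n
    diff = auc_a - auc_b
    z = diff / np.sqrt(var)
    return diff, z


def anova_icc31(x):
    """Hand computation of ICC(3,1) from explicit sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum(k * (row.mean() - grand) ** 2 for row in x) / (n - 1)
    sse = 0.0
    col_means = [x[:, j].mean() for j in range(k)]
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - col_means[j] + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


# ------------------------------------------------------------ identities
class TestIdentities:
    def test_youden_reported_rows(self):
        # printed sensitivity/specificity rows round to the printed J values
        assert round(youden_index(0.846, 0.778), 2) == 0.62
        assert round(youden_index(0.800, 0.909), 2) == 0.71
        assert round(youden_index(1.000, 0.037), 2) == 0.04

    def test_auc_difference(self):
        assert auc_difference(0.902, 0.757) == pytest.approx(0.145)
        assert auc_difference(0.902, 0.837) == pytest.approx(0.065)


# ------------------------------------------------------------- univariate
class TestUnivariateCompare:
    def test_identical_groups_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = univariate_compare(g, g)
        assert res.p > 0.9

    def test_power_at_two_pooled_sd(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(30)
            b = rng.standard_normal(30) + 2.0
            if univariate_compare(a, b).p < 0.001:
                hits += 1
        assert hits >= 190  # >= 95% of runs

    def test_skewed_data_takes_mann_whitney(self):
        rng = np.random.default_rng(3)
        a = np.exp(2.0 * rng.standard_normal(60))  # heavily lognormal
        b = np.exp(2.0 * rng.standard_normal(60))
        # oracle: Shapiro-Wilk itself rejects normality for these draws
        assert sps.shapiro(a).pvalue < 0.05
        res = univariate_compare(a, b)
        assert res.test == "mann-whitney"

    def test_constant_group_falls_through(self):
        res = univariate_compare([5.0] * 10, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.test == "mann-whitney"
        assert res.log

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            univariate_compare([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_normal_data_takes_t_test(self, rng):
        a = rng.standard_normal(40)
        b = rng.standard_normal(40)
        res = univariate_compare(a, b)
        assert res.test == "t-test"
        # oracle: scipy's pooled t-test on the same data
        assert res.p == pytest.approx(sps.ttest_ind(a, b).pvalue)


# -------------------------------------------------------------------- ROC
class TestRocWithYouden:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        r = roc_with_youden(s, y)
        assert r.auc == 1.0
        assert r.youden == pytest.approx(1.0)
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.cutoff == pytest.approx(0.7)  # lowest maximizing threshold

    def test_youden_identity_always(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            s = rng.standard_normal(40)
            r = roc_with_youden(s, y)
            assert r.youden == pytest.approx(r.sensitivity + r.specificity - 1)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = np.r_[np.ones(15, int), np.zeros(25, int)]
        s = rng.standard_normal(40)
        s[5] = s[20]  # inject a tie across classes
        assert roc_with_youden(s, y).auc == pytest.approx(roc_auc_score(y, s))

    def test_constant_scores_degenerate(self):
        r = roc_with_youden(np.ones(20), np.r_[np.ones(10, int), np.zeros(10, int)])
        assert r.auc == 0.5
        assert np.isnan(r.cutoff) and r.degenerate

    def test_null_coverage(self):
        inside = 0
        runs = 100
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(100, int), np.zeros(100, int)]
            s = rng.standard_normal(200)
            r = roc_with_youden(s, y)
            inside += r.ci_low <= 0.5 <= r.ci_high
        assert inside >= 0.89 * runs  # ~95% coverage with MC slack

    def test_complement_and_monotone_invariance(self, rng):
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        s = rng.standard_normal(40)
        a1 = roc_with_youden(s, y).auc
        assert roc_with_youden(-s, y).auc == pytest.approx(1.0 - a1)
        assert roc_with_youden(np.exp(s), y).auc == pytest.approx(a1)


class TestDelongCompare:
    def test_self_comparison(self, rng):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        s = rng.standard_normal(20)
        d = delong_compare(s, s.copy(), y)
        assert d.difference == 0.0 and d.z == 0.0 and d.p == 1.0

    def test_monotone_transform_zero_difference(self, rng):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        s = rng.standard_normal(20)
        d = delong_compare(s, 3.0 * s + 7.0, y)
        assert d.difference == pytest.approx(0.0, abs=1e-12)
        assert d.p == pytest.approx(1.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(21)
        y = np.r_[np.ones(8, int), np.zeros(12, int)]
        sa = rng.standard_normal(20) + y
        sb = rng.standard_normal(20) + 0.5 * y
        d = delong_compare(sa, sb, y)
        diff, z = naive_delong(sa, sb, y)
        assert d.difference == pytest.approx(diff, abs=1e-12)
        assert d.z == pytest.approx(z, abs=1e-8)

    def test_matches_naive_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        sa = rng.integers(0, 4, 20).astype(float)  # heavy ties
        sb = rng.integers(0, 4, 20).astype(float)
        d = delong_compare(sa, sb, y)
        diff, z = naive_delong(sa, sb, y)
        assert d.difference == pytest.approx(diff, abs=1e-12)
        assert d.z == pytest.approx(z, abs=1e-8)

    def test_too_few_subjects_error(self):
        with pytest.raises(ValueError):
            delong_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 0, 0])


# --------------------------------------------------------- stepwise logistic
def _signal_table(n=400, seed=0):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.standard_normal((n, 6)),
                     columns=[f"f{i}" for i in range(6)])
    eta = 1.5 * x["f0"] - 0.5
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return x, y


class TestStepwiseLogistic:
    def test_informative_feature_selected(self):
        hits = 0
        runs = 40
        for seed in range(runs):
            x, y = _signal_table(seed=seed)
            if len(np.unique(y)) < 2:
                continue
            m = stepwise_logistic(x, y, direction="backward")
            hits += "f0" in m.selected_features
        assert hits >= 0.9 * runs

    def test_null_mostly_empty(self):
        empties = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            x = pd.DataFrame(rng.standard_normal((200, 5)),
                             columns=list("abcde"))
            y = rng.integers(0, 2, 200)
            m = stepwise_logistic(x, y)
            empties += len(m.selected_features) == 0
        # with p_remove=0.10 each pure-noise feature survives w.p. ~0.1
        assert empties >= 0.4 * runs

    def test_selected_subset_optimal_among_same_size(self):
        import itertools

        import statsmodels.api as sm

        x, y = _signal_table(n=300, seed=7)
        x = x[["f0", "f1", "f2"]]
        m = stepwise_logistic(x, y, direction="backward")
        k = len(m.selected_features)
        assert k >= 1
        best_llf = -np.inf
        for combo in itertools.combinations(x.columns, k):
            fit = sm.Logit(y, sm.add_constant(x[list(combo)])).fit(disp=0)
            best_llf = max(best_llf, fit.llf)
        assert m.llf == pytest.approx(best_llf, abs=1e-6)

    def test_forward_direction(self):
        x, y = _signal_table(seed=3)
        m = stepwise_logistic(x, y, direction="forward")
        assert "f0" in m.selected_features
        assert m.selection_path[0] == ("start", ())

    def test_perfect_separation_flagged(self):
        x = pd.DataFrame({"a": np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        m = stepwise_logistic(x, y)
        assert m.separation
        assert m.warnings
        assert np.all(np.isfinite(list(m.coefficients.values())))

    def test_missing_values_rejected(self):
        x = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError):
            stepwise_logistic(x, [0, 1, 0])

    def test_nesting_property(self):
        """Adding a feature never decreases the maximized log-likelihood."""
        import statsmodels.api as sm

        x, y = _signal_table(n=200, seed=11)
        llf_small = sm.Logit(y, sm.add_constant(x[["f0"]])).fit(disp=0).llf
        llf_big = sm.Logit(y, sm.add_constant(x[["f0", "f1"]])).fit(disp=0).llf
        assert llf_big >= llf_small - 1e-9


# ------------------------------------------------------------- calibration
class TestHosmerLemeshow:
    def test_perfectly_calibrated_deciles(self):
        # observed equals expected in every group -> statistic 0
        p = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
        y = np.concatenate([
            [1] * 2 + [0] * 8, [1] * 4 + [0] * 6, [1] * 6 + [0] * 4, [1] * 8 + [0] * 2,
        ])
        stat, pval, _ = hosmer_lemeshow(p, y, n_groups=4)
        assert stat == pytest.approx(0.0)
        assert pval == pytest.approx(1.0)

    def test_merged_groups_logged(self, rng):
        p = np.repeat([0.3, 0.5, 0.7, 0.9], 25)
        y = (rng.random(100) < p).astype(int)
        _, _, log = hosmer_lemeshow(p, y, n_groups=10)
        assert log and "merged" in log[0]

    def test_probability_domain(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0, 0.5, 0.7], [0, 1, 1])

    def test_miscalibrated_rejects(self):
        rejections = 0
        runs = 100
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.05, 0.95, 400)
            y = (rng.random(400) < p).astype(int)
            _, pval, _ = hosmer_lemeshow(p**2, y)  # systematically squared
            rejections += pval < 0.05
        assert rejections > 0.5 * runs


# -------------------------------------------------------------------- ICC
class TestIcc:
    def test_duplicate_columns(self, rng):
        a = rng.standard_normal(10)
        res = icc_two_way_mixed(np.c_[a, a])
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.band == "excellent"

    def test_constant_offset_consistency_one(self, rng):
        a = rng.standard_normal(12)
        res = icc_two_way_mixed(np.c_[a, a + 5.0])
        assert res.icc == pytest.approx(1.0)
        agr = icc_two_way_mixed(np.c_[a, a + 5.0], form="agreement")
        assert agr.icc < 0.9  # the offset counts against absolute agreement

    def test_six_by_two_anova_oracle(self):
        x = np.array([
            [9.0, 10.0], [6.0, 7.0], [8.0, 8.5], [7.0, 6.0], [10.0, 10.5], [6.5, 7.5],
        ])
        res = icc_two_way_mixed(x)
        assert res.icc == pytest.approx(anova_icc31(x), abs=1e-10)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal((8, 3)) + 2 * rng.standard_normal((8, 1))
            res = icc_two_way_mixed(x)
            assert res.icc == pytest.approx(anova_icc31(x), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        x = rng.standard_normal((12, 2)) + 1.5 * rng.standard_normal((12, 1))
        res = icc_two_way_mixed(x)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": x.ravel(),
        })
        tab = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = tab[tab["Type"].astype(str).str.contains(r"C,\s*1")].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=5e-3)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=5e-3)

    def test_zero_between_subject_variance_undefined(self):
        x = np.zeros((6, 2))
        res = icc_two_way_mixed(x)
        assert np.isnan(res.icc) and res.band == "undefined"

    def test_band_cut_points(self):
        from t1liver.stats import _icc_band

        assert _icc_band(0.15) == "poor"
        assert _icc_band(0.200) == "poor"
        assert _icc_band(0.35) == "fair"
        assert _icc_band(0.55) == "moderate"
        assert _icc_band(0.75) == "good"
        assert _icc_band(0.801) == "excellent"

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            icc_two_way_mixed(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            icc_two_way_mixed(np.zeros((8, 1)))
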