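"""Statistical chain for the risk-stratification analysis.

Normality-gated two-group comparison, stepwise binary logistic
regression, empirical ROC with Youden-index cutoffs and DeLong variance,
paired DeLong AUC comparison, Hosmer-Lemeshow calibration, and the
two-way mixed-model intraclass correlation.  Two-sided p-values
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "UnivariateResult",
    "RocResult",
    "DelongResult",
    "LogisticModel",
    "IccResult",
    "youden_index",
    "auc_difference",
    "univariate_compare",
    "roc_with_youden",
    "delong_compare",
    "stepwise_logistic",
    "hosmer_lemeshow",
    "icc_two_way_mixed",
]

ALPHA_NORMALITY = 0.05


# ----------------------------------------------------------------- identities
def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden J = sensitivity + specificity - 1 (inputs as fractions)."""
    return sensitivity + specificity - 1.0


def auc_difference(auc_a: float, auc_b: float) -> float:
    """Signed AUC difference between two models, a - b."""
    return auc_a - auc_b


# ------------------------------------------------------------ univariate gate
@dataclass
class UnivariateResult:
    test: str  # "t-test" | "mann-whitney"
    p: float
    statistic: float
    shapiro_p: tuple[float, float]
    log: list[str] = field(default_factory=list)


def _shapiro_p(x: np.ndarray, log: list[str]) -> float:
    if np.ptp(x) == 0:
        log.append("constant group: Shapiro-Wilk undefined, forcing Mann-Whitney")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(sps.shapiro(x).pvalue)
        except Exception:  # pragma: no cover - scipy edge cases
            log.append("Shapiro-Wilk failed, forcing Mann-Whitney")
            return 0.0


def univariate_compare(group_a, group_b, alpha: float = ALPHA_NORMALITY) -> UnivariateResult:
    """Two-group comparison gated on Shapiro-Wilk normality of each group.

    Both groups normal at ``alpha`` -> Student's t test (pooled variance);
    otherwise Mann-Whitney U.  The result names the test that ran.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    log: list[str] = []
    pa, pb = _shapiro_p(a, log), _shapiro_p(b, log)
    if pa > alpha and pb > alpha:
        res = sps.ttest_ind(a, b, equal_var=True)
        return UnivariateResult("t-test", float(res.pvalue), float(res.statistic), (pa, pb), log)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return UnivariateResult("mann-whitney", float(res.pvalue), float(res.statistic), (pa, pb), log)


# ------------------------------------------------------------------ ROC/AUC
@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    degenerate: bool = False


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not set(np.unique(y)) <= {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes coded 0/1")
    return y


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Midrank structural components: (auc, v10 over positives, v01 over negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_s = np.concatenate([pos, neg])
    tz = sps.rankdata(all_s)  # midranks in the pooled sample
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return auc, v10, v01


def roc_with_youden(scores, labels, ci_level: float = 0.95) -> RocResult:
    """Empirical ROC with a maximal-Youden cutoff and a DeLong-variance CI.

    Positivity is ``score >= cutoff``.  Ties in J resolve to the lowest
    threshold.  Constant scores yield AUC 0.5 with the cutoff flagged
    undefined (NaN).
    """
    s = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    if np.ptp(s) == 0:
        return RocResult(0.5, 0.5, 0.5, float("nan"), float("nan"), float("nan"),
                         float("nan"), degenerate=True)

    auc, v10, v01 = _delong_components(s, y)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = sps.norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(max(var, 0.0))
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    thresholds = np.unique(s)
    pred = s[None, :] >= thresholds[:, None]  # (T, N)
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    sens = tp / m
    spec = 1.0 - fp / n
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest) threshold on ties
    return RocResult(
        float(auc), float(ci_low), float(ci_high),
        float(thresholds[best]), float(sens[best]), float(spec[best]), float(j[best]),
    )


@dataclass
class DelongResult:
    difference: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def delong_compare(scores_a, scores_b, labels, ci_level: float = 0.95) -> DelongResult:
    """DeLong test for two correlated AUCs measured on the same subjects."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _check_labels(labels)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("paired scores must share the subjects of `labels`")
    m, n = int((y == 1).sum()), int((y == 0).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 subjects per class")

    auc_a, v10_a, v01_a = _delong_components(sa, y)
    auc_b, v10_b, v01_b = _delong_components(sb, y)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        zval = 0.0 if diff == 0 else float("inf") * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return DelongResult(float(diff), float(diff), float(diff), float(zval), float(p))
    se = float(np.sqrt(var))
    zval = diff / se
    p = 2 * sps.norm.sf(abs(zval))
    zc = sps.norm.ppf(0.5 + ci_level / 2)
    return DelongResult(float(diff), float(diff - zc * se), float(diff + zc * se),
                        float(zval), float(p))


# --------------------------------------------------------- stepwise logistic
@dataclass
class LogisticModel:
    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    selection_path: list[tuple]
    hl_p: float
    separation: bool = False
    llf: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted probability of the positive class."""
        eta = self.intercept + sum(
            self.coefficients[f] * table[f].to_numpy(dtype=float)
            for f in self.selected_features
        )
        return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


def _fit_logit(x: pd.DataFrame, y: np.ndarray):
    """ML logistic fit; returns (results, separation_flag)."""
    design = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            return None, True
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 1e3):
        return res, True
    return res, False


def _penalized_fallback(x: pd.DataFrame, y: np.ndarray):
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=100.0, max_iter=2000)  # default L2 penalty
    clf.fit(x.to_numpy(dtype=float), y)
    coefs = dict(zip(x.columns, clf.coef_[0]))
    return coefs, float(clf.intercept_[0])


def stepwise_logistic(
    features: pd.DataFrame,
    labels,
    direction: str = "backward",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> LogisticModel:
    """Stepwise maximum-likelihood logistic regression.

    Backward: start full, iteratively drop the worst Wald p > ``p_remove``.
    Forward: add the best likelihood-ratio p < ``p_enter``, purging
    additions whose Wald p rises above ``p_remove``.  Perfect separation
    falls back to an L2-penalised fit and is flagged.
    """
    if features.isna().any().any():
        raise ValueError("features contain missing values")
    y = _check_labels(labels)
    names = list(features.columns)
    path: list[tuple] = []
    warn: list[str] = []

    def wald_p(res, cols):
        return {c: float(res.pvalues[c]) for c in cols}

    if direction == "backward":
        current = list(names)
        path.append(("start", tuple(current)))
        res, sep = _fit_logit(features[current], y)
        while current and not sep:
            pv = wald_p(res, current)
            worst = max(pv, key=pv.get)
            if pv[worst] <= p_remove:
                break
            current.remove(worst)
            path.append(("drop", worst, pv[worst]))
            if current:
                res, sep = _fit_logit(features[current], y)
    elif direction == "forward":
        current = []
        path.append(("start", ()))
        res, sep = _fit_logit(features[current], y) if current else (None, False)
        ll0_res, sep0 = _fit_logit(features[[]], y)
        sep = sep0
        res = ll0_res
        while not sep:
            remaining = [c for c in names if c not in current]
            if not remaining:
                break
            ll0 = res.llf
            best_c, best_p = None, 1.0
            for c in remaining:
                cand, csep = _fit_logit(features[current + [c]], y)
                if csep or cand is None:
                    continue
                lr = 2 * (cand.llf - ll0)
                p = float(sps.chi2.sf(max(lr, 0.0), 1))
                if p < best_p:
                    best_c, best_p, best_res = c, p, cand
            if best_c is None or best_p >= p_enter:
                break
            current.append(best_c)
            res = best_res
            path.append(("add", best_c, best_p))
            # backward purge of the working set
            changed = True
            while changed and len(current) > 1:
                changed = False
                pv = wald_p(res, current)
                worst = max(pv, key=pv.get)
                if pv[worst] > p_remove:
                    current.remove(worst)
                    path.append(("drop", worst, pv[worst]))
                    res, sep = _fit_logit(features[current], y)
                    changed = not sep
    else:
        raise ValueError("direction must be 'backward' or 'forward'")

    if sep:
        warn.append("perfect separation detected: coefficients from penalized fit")
        coefs, intercept = _penalized_fallback(features[current] if current else features, y)
        selected = list(coefs)
        llf = float("nan")
    else:
        final, sep2 = _fit_logit(features[current], y) if current is not None else (None, False)
        if final is None or sep2:
            warn.append("final refit separated: coefficients from penalized fit")
            coefs, intercept = _penalized_fallback(features[current], y)
            selected, llf, sep = list(coefs), float("nan"), True
        else:
            selected = list(current)
            coefs = {c: float(final.params[c]) for c in selected}
            intercept = float(final.params["const"])
            llf = float(final.llf)

    model = LogisticModel(selected, coefs, intercept, path, hl_p=float("nan"),
                          separation=sep, llf=llf, warnings=warn)
    probs = model.predict(features)
    if np.all((probs > 0) & (probs < 1)) and len(np.unique(probs)) > 2:
        try:
            _, hl_p, _ = hosmer_lemeshow(probs, y)
            model.hl_p = hl_p
        except ValueError:
            pass
    return model


# ------------------------------------------------------------ calibration
def hosmer_lemeshow(probs, labels, n_groups: int = 10):
    """Hosmer-Lemeshow decile-of-risk goodness-of-fit test.

    Returns (statistic, p, log).  Subjects sort by predicted probability
    into ``n_groups`` near-equal groups; the statistic is chi-square with
    ``n_groups - 2`` degrees of freedom.  When there are fewer distinct
    probabilities than groups, groups are merged and the merge is logged.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    log: list[str] = []
    n_distinct = len(np.unique(p))
    g = min(n_groups, n_distinct)
    if g < n_groups:
        log.append(f"merged to {g} groups ({n_distinct} distinct probabilities)")
    if g < 3:
        raise ValueError("need at least 3 groups for a chi-square statistic")
    order = np.argsort(p, kind="stable")
    chunks = np.array_split(order, g)
    stat = 0.0
    for ch in chunks:
        ng = ch.size
        obs = y[ch].sum()
        pbar = p[ch].mean()
        exp = ng * pbar
        denom = exp * (1 - pbar)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
    pval = float(sps.chi2.sf(stat, g - 2))
    return float(stat), pval, log


# --------------------------------------------------------------------- ICC
@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    form: str


def _icc_band(icc: float) -> str:
    if np.isnan(icc):
        return "undefined"
    if icc <= 0.200:
        return "poor"
    if icc <= 0.400:
        return "fair"
    if icc <= 0.600:
        return "moderate"
    if icc <= 0.800:
        return "good"
    return "excellent"


def icc_two_way_mixed(
    ratings,
    form: str = "consistency",
    ci_level: float = 0.95,
) -> IccResult:
    """Single-measure two-way mixed-model ICC from ANOVA mean squares.

    ``ratings`` is subjects x raters with no missing cells.  The default
    consistency form is ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE) with an
    exact F-based confidence interval; ``form='agreement'`` gives the
    absolute-agreement single-measure coefficient.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    n, k = x.shape
    if k < 2 or n < 5:
        raise ValueError("need >= 2 raters and >= 5 subjects")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    alpha = 1 - ci_level
    if msr <= 0 and mse <= 0:
        return IccResult(float("nan"), float("nan"), float("nan"), "undefined", form)

    if form == "consistency":
        if mse == 0.0:
            return IccResult(1.0, 1.0, 1.0, "excellent", form)
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif form == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0.0:
            return IccResult(1.0, 1.0, 1.0, "excellent", form)
        icc = (msr - mse) / denom
        # McGraw & Wong (1996) Satterthwaite CI for ICC(A,1)
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else float("inf")
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else float("inf")
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr
            )
        else:
            lo = hi = icc
    else:
        raise ValueError("form must be 'consistency' or 'agreement'")

    icc = float(min(icc, 1.0))
    return IccResult(icc, float(min(lo, 1.0)), float(min(hi, 1.0)), _icc_band(icc), form)
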