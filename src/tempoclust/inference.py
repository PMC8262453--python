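"""Linear-scale group comparisons, descriptive moments, and the
cluster-wise normalized regression.

ANOVA sums of squares, the pooled t test, and Spearman's rank correlation
are computed from first principles (they are cross-checked against scipy in
the test suite); Tukey HSD p-values use scipy's studentized-range
distribution, Holm adjustment comes from statsmodels, and the multiple
regression is an ordinary least squares fit via statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_sq: float  # SS_between / SS_total
    group_labels: list = field(default_factory=list)
    group_means: list = field(default_factory=list)
    group_ns: list = field(default_factory=list)
    tukey: list[dict] = field(default_factory=list)


@dataclass
class RegressionResult:
    coefficients: dict  # per-predictor beta (standardized by default)
    p_values: dict
    intercept: float
    r_squared: float
    F: float
    df_model: int
    df_resid: int
    p_model: float
    standardized: bool


@dataclass
class MomentsResult:
    skewness: float  # bias-adjusted G1
    se_skewness: float
    kurtosis: float  # bias-adjusted excess kurtosis G2
    se_kurtosis: float
    n: int


def anova_oneway(values: Sequence[float], groups: Sequence, with_tukey: bool = True) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA with Tukey HSD post-hocs.

    F is built from explicit between/within sums of squares so that
    eta_sq = SS_between/SS_total is exact; all-equal groups with zero
    within-group variance yield F = 0 by convention.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = [lab for lab in pd.unique(g)]
    parts = [y[g == lab] for lab in labels]
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    if any(p.size < 2 for p in parts):
        raise ValueError("every group needs n >= 2")
    N, k = y.size, len(parts)
    grand = y.mean()
    ss_between = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts)
    ss_total = ss_between + ss_within
    df1, df2 = k - 1, N - k
    if ss_within <= 0:
        F = 0.0 if ss_between <= 0 else float("inf")
        p_val = 1.0 if ss_between <= 0 else 0.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p_val = float(stats.f.sf(F, df1, df2))
    eta_sq = float(ss_between / ss_total) if ss_total > 0 else 0.0

    result = AnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p=p_val,
        eta_sq=eta_sq,
        group_labels=list(labels),
        group_means=[float(p.mean()) for p in parts],
        group_ns=[int(p.size) for p in parts],
    )
    if with_tukey and ss_within > 0:
        msw = ss_within / df2
        for i, j in combinations(range(k), 2):
            a, b = parts[i], parts[j]
            diff = a.mean() - b.mean()
            se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df2))
            result.tukey.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(diff),
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                }
            )
    return result


def two_group_compare(values: Sequence[float], groups: Sequence) -> tuple[float, float, float]:
    """Pooled-SD two-sample t test and Cohen's d.

    Returns ``(t, p, d)`` with d = mean difference / pooled SD.  d is nan
    (flagged via warning) when the pooled SD is zero.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("two_group_compare needs exactly 2 groups")
    a, b = y[g == labels[0]], y[g == labels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    na, nb = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    sp = np.sqrt(sp2)
    diff = a.mean() - b.mean()
    if sp == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, 0.0
        warnings.warn("zero pooled SD: Cohen's d undefined", stacklevel=2)
        return float("inf") * np.sign(diff), 0.0, float("nan")
    t = diff / (sp * np.sqrt(1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), na + nb - 2))
    return float(t), p, float(diff / sp)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p from the t approximation t = rho*sqrt((n-2)/(1-rho^2)).  Constant
    input makes rho undefined (nan, with a warning).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("constant input: Spearman's rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rx = stats.rankdata(xa)  # average ranks for ties
    ry = stats.rankdata(ya)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
    n = xa.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, p


def moments(values: Sequence[float]) -> MomentsResult:
    """Bias-adjusted sample skewness and excess kurtosis with standard errors.

    SE_skew = sqrt(6n(n-1)/((n-2)(n+1)(n+3)));
    SE_kurt = 2 * SE_skew * sqrt((n^2-1)/((n-3)(n+5))).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for adjusted moments")
    if np.ptp(x) == 0:
        warnings.warn("zero variance: moments undefined", stacklevel=2)
        return MomentsResult(float("nan"), float("nan"), float("nan"), float("nan"), n)
    g1 = float(stats.skew(x, bias=False))
    g2 = float(stats.kurtosis(x, fisher=True, bias=False))
    se_s = se_skewness(n)
    se_k = se_kurtosis(n)
    return MomentsResult(g1, se_s, g2, se_k, n)


def se_skewness(n: int) -> float:
    return float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))


def se_kurtosis(n: int) -> float:
    return float(2.0 * se_skewness(n) * np.sqrt((n * n - 1.0) / ((n - 3) * (n + 5))))


def clusterwise_z(values: Sequence[float], assignments: Sequence) -> np.ndarray:
    """Standardize within each cluster: (x - cluster mean) / cluster sample SD.

    Puts all tempo clusters on a common scale so faster/slower-than-cluster
    comparisons work across modes.  Singleton clusters get z = 0 with a
    warning.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(assignments)
    z = np.empty_like(y)
    for lab in pd.unique(a):
        mask = a == lab
        sub = y[mask]
        if sub.size == 1:
            warnings.warn(f"singleton cluster {lab!r}: z set to 0", stacklevel=2)
            z[mask] = 0.0
            continue
        sd = sub.std(ddof=1)
        if sd == 0:
            warnings.warn(f"cluster {lab!r} has zero SD: z set to 0", stacklevel=2)
            z[mask] = 0.0
        else:
            z[mask] = (sub - sub.mean()) / sd
    return z


def fit_regression(
    z_values: Sequence[float],
    predictors: Mapping[str, Sequence[float]] | pd.DataFrame,
    standardize: bool = True,
    condition_threshold: float = 1e8,
) -> RegressionResult:
    """OLS of the cluster-normalized outcome on the predictors.

    With ``standardize=True`` (default) predictors are z-scored so the
    coefficients are standardized betas; set False for raw-scale slopes.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(z_values, dtype=float)
    if len(X) != y.size:
        raise ValueError("outcome and predictors must have equal length")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need N > number of predictors + 1")
    if standardize:
        X = (X - X.mean()) / X.std(ddof=1)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.cond(design.to_numpy()) > condition_threshold:
        warnings.warn("predictors are nearly collinear", stacklevel=2)
    fit = sm.OLS(y, design).fit()
    coefs = {c: float(fit.params[c]) for c in X.columns}
    pvals = {c: float(fit.pvalues[c]) for c in X.columns}
    return RegressionResult(
        coefficients=coefs,
        p_values=pvals,
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        F=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p_model=float(fit.f_pvalue),
        standardized=standardize,
    )
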