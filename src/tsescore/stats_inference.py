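"""Evaluation statistics: ROC/AUC with DeLong comparison, exact Fisher test,
rank tests, Benjamini-Hochberg adjustment, logistic regression, and
Kaplan-Meier / log-rank / Cox survival analysis.

AUCs use the midrank (Mann-Whitney) estimator, so tied scores count 1/2 and
the point estimate agrees exactly with all-pairs concordance counting.  The
DeLong variance/covariance uses the structural-components formulation on the
same midranks.  Fisher's two-sided p is the probability-mass method computed
in exact integer arithmetic.  Survival fits are delegated to lifelines
(Kaplan-Meier product-limit, log-rank, Cox with Efron tie handling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import lifelines
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "ROCResult",
    "SurvivalFit",
    "SeparationError",
    "roc_auc",
    "delong_test",
    "delong_variance",
    "fisher_exact",
    "rank_tests",
    "bh_adjust",
    "logistic_fit",
    "km_fit",
    "logrank",
    "cox_fit",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    auc: float
    variance: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray


def _check_binary(label: np.ndarray) -> np.ndarray:
    label = np.asarray(label)
    uniq = set(np.unique(label).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    label = label.astype(int)
    if label.min() == label.max():
        raise ValueError("both classes must be present")
    return label


def _midrank_components(score: np.ndarray, label: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-observation structural components (V10, V01) and the AUC."""
    pos = score[label == 1]
    neg = score[label == 0]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    # placement of each positive among negatives, and vice versa
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def roc_auc(score, label) -> ROCResult:
    """Midrank AUC with DeLong variance and the empirical ROC curve.

    The AUC equals the all-pairs concordance count with ties scored 1/2.
    """
    score = np.asarray(score, dtype=float)
    label = _check_binary(label)
    if score.shape != label.shape:
        raise ValueError("score and label must be aligned")
    v10, v01, auc = _midrank_components(score, label)
    m, n = len(v10), len(v01)
    if m > 1 and n > 1:
        variance = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    else:
        variance = float("nan")
    fpr, tpr = _roc_curve(score, label)
    return ROCResult(auc=auc, variance=variance, n_pos=m, n_neg=n, fpr=fpr, tpr=tpr)


def _roc_curve(score: np.ndarray, label: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve over all distinct thresholds, from (0,0) to (1,1)."""
    order = np.argsort(-score, kind="mergesort")
    s, y = score[order], label[order]
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y)[idx]
    fp = np.cumsum(1 - y)[idx]
    tpr = np.r_[0.0, tp / tp[-1]]
    fpr = np.r_[0.0, fp / fp[-1]]
    return fpr, tpr


def delong_variance(score, label) -> float:
    """DeLong variance of a single midrank AUC."""
    return roc_auc(score, label).variance


def delong_test(score_a, score_b, label) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated (paired) AUCs.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    label = _check_binary(label)
    if score_a.shape != score_b.shape or score_a.shape != label.shape:
        raise ValueError("scores must be paired on the same samples")
    if label.sum() < 2 or (1 - label).sum() < 2:
        raise ValueError("need >= 2 observations in each class")
    va10, va01, auc_a = _midrank_components(score_a, label)
    vb10, vb01, auc_b = _midrank_components(score_b, label)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if auc_a == auc_b:
        return auc_a, auc_b, 0.0, 1.0
    if var_diff <= 0:
        z = math.inf if auc_a > auc_b else -math.inf
    else:
        z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2 * sps.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return auc_a, auc_b, float(z), float(p)


# ---------------------------------------------------------------------------
# Fisher's exact test (probability-mass two-sided definition, exact integers)
# ---------------------------------------------------------------------------


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed one.
    Computed with exact integer arithmetic, so it is free of the float
    tie-breaking issues of pmf-comparison implementations.  Returns
    ``(sample odds ratio, p)``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if n == 0:
        return odds, 1.0
    # numerator weights C(r1,k) * C(r2,c1-k) over the support of k
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    numer = sum(w for w in weights if w <= observed)
    p = numer / math.comb(n, c1)
    return odds, min(1.0, float(p))


# ---------------------------------------------------------------------------
# Rank tests and multiplicity
# ---------------------------------------------------------------------------


def rank_tests(groups) -> tuple[float, float, str]:
    """Wilcoxon rank-sum for 2 groups, Kruskal-Wallis for more.

    Returns ``(statistic, p, test_name)``; midrank tie correction and the
    normal / chi-square approximation are applied.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if len(groups) == 2:
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue), "wilcoxon-rank-sum"
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue), "kruskal-wallis"


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------


def logistic_fit(
    X,
    y,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares.

    Convergence: change in log-likelihood below ``tol``.  Complete or
    quasi-complete separation raises :class:`SeparationError` rather than
    returning runaway coefficients.  Returns a frame with ``coef``, ``se``,
    ``z`` and ``p`` (Wald) per column of the design.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        if np.max(np.abs(beta)) > 1e2 or np.all(w < 1e-10):
            raise SeparationError("complete or quasi-complete separation detected")
        z = eta + (y - mu) / np.maximum(w, 1e-10)
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        eta = np.clip(X @ beta, -700, 700)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    else:
        if np.max(np.abs(beta)) > 1e2:
            raise SeparationError("complete or quasi-complete separation detected")
        raise RuntimeError("IRLS did not converge")
    eta = X @ beta
    # perfect prediction at large |eta| means the MLE diverges
    if np.max(np.abs(eta)) > 15 and np.all((eta > 0) == (y == 1)):
        raise SeparationError("complete or quasi-complete separation detected")
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pval = 2 * sps.norm.sf(np.abs(zval))
    return pd.DataFrame({"coef": beta, "se": se, "z": zval, "p": pval}, index=names)


# ---------------------------------------------------------------------------
# Survival (lifelines-backed)
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    times: np.ndarray
    events: np.ndarray
    km_times: np.ndarray
    km_survival: np.ndarray


def _check_survival(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must be aligned")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be binary 0/1")
    return times, events


def km_fit(times, events) -> SurvivalFit:
    """Kaplan-Meier product-limit estimator."""
    times, events = _check_survival(times, events)
    if events.sum() == 0:
        raise ValueError("need >= 1 event")
    kmf = lifelines.KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return SurvivalFit(
        times=times,
        events=events,
        km_times=sf.index.to_numpy(dtype=float),
        km_survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def logrank(times, events, groups) -> tuple[float, float]:
    """Log-rank test across 2+ groups (observed-vs-expected hypergeometric sums)."""
    times, events = _check_survival(times, events)
    groups = np.asarray(groups)
    if groups.shape != times.shape:
        raise ValueError("groups must be aligned with times")
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 groups")
    if events.sum() == 0:
        raise ValueError("all observations censored")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(times, events, covariates) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron tie handling, Wald CIs).

    ``covariates`` is a DataFrame or 2-D array; returns one row per covariate
    with ``coef``, ``hr``, ``hr_lower``, ``hr_upper``, ``se``, ``p``.
    """
    times, events = _check_survival(times, events)
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.reset_index(drop=True)
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cov = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    frame = cov.copy()
    frame["time"] = times
    frame["event"] = events
    cph = lifelines.CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    summary = cph.summary
    return pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "hr_lower": summary["exp(coef) lower 95%"],
            "hr_upper": summary["exp(coef) upper 95%"],
            "se": summary["se(coef)"],
            "p": summary["p"],
        }
    )
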