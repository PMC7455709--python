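"""Survival stratification by signature index.

Patients are split into High/Low groups by index tertile (top ceil(n/3) =
High), compared with Kaplan-Meier curves and the log-rank (Mantel-Cox)
test, and modeled with Cox proportional hazards, univariate (index only) or
multivariate (index + age + metastatic status + subgroup).

KM estimation and the log-rank test are delegated to lifelines; the Cox
partial likelihood (Efron tie correction) is maximized here by Newton
iteration with step-halving, which also exposes the score test at beta = 0
and the per-iteration log-likelihood trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist

__all__ = ["KMEstimate", "CoxFit", "tertile_split", "km_curve", "logrank", "cox_fit"]


@dataclass
class KMEstimate:
    times: np.ndarray            # distinct event/censor times of the step function
    survival: np.ndarray         # S(t) just after each time
    at_risk: np.ndarray
    median: float | None         # smallest t with S(t) <= 0.5; None if never reached
    censor_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class CoxFit:
    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    ll_trace: list[float] = field(default_factory=list)
    score_chi2_null: float | None = None  # score test of all coefs = 0
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratio,
                "p": self.p,
            },
            index=self.covariates,
        )


def tertile_split(indices: pd.Series) -> pd.Series:
    """Label the top ceil(n/3) patients by index 'High', the rest 'Low'.

    Boundary ties are broken by stable patient order: among equal indices
    the patient appearing first in the input wins the High slot.
    """
    s = pd.Series(indices)
    n = len(s)
    if n < 3:
        raise ValueError("tertile split needs at least 3 patients")
    n_high = math.ceil(n / 3)
    order = np.argsort(-s.to_numpy(), kind="stable")
    labels = np.array(["Low"] * n, dtype=object)
    labels[order[:n_high]] = "High"
    return pd.Series(labels, index=s.index, name="group")


def km_curve(times, events) -> KMEstimate:
    """Product-limit (Kaplan-Meier) survival estimate.

    The median is the smallest observed time with S(t) <= 0.5 and is None
    ("undetermined") when the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    # drop the t=0 anchor row unless an event/censoring occurred at 0
    mask = table.index > 0 if (times > 0).all() else np.ones(len(table), bool)
    med = kmf.median_survival_time_
    return KMEstimate(
        times=table.index.to_numpy()[mask],
        survival=surv.to_numpy()[mask],
        at_risk=table["at_risk"].to_numpy()[mask],
        median=None if np.isinf(med) else float(med),
        censor_times=np.sort(times[events == 0]),
    )


def logrank(times, events, groups) -> tuple[float, int, float]:
    """Mantel-Cox log-rank test across >= 2 groups.

    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 nonempty groups")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(times, groups, events)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def _design_matrix(
    cohort: pd.DataFrame, covariates: list[str], subgroup_reference: str | None = None
) -> pd.DataFrame:
    cols = []
    for cov in covariates:
        col = cohort[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            ref = subgroup_reference or levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append(
                    pd.Series((col.astype(str) == lev).astype(float), name=f"{cov}[{lev}]")
                )
        else:
            cols.append(pd.Series(col.astype(float), name=cov))
    X = pd.concat(cols, axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after dummy coding")
    return X


def _efron_loglik(beta, X, time, event):
    """Efron-tie Cox log partial likelihood with gradient and information.

    Rows must be sorted by time ascending.  Returns (ll, grad, info).
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    # risk-set sums via reverse cumulative sums (rows sorted by time)
    s0 = np.cumsum(w[::-1])[::-1]                     # sum of w over at-risk
    s1 = np.cumsum((w[:, None] * X)[::-1], 0)[::-1]   # weighted X sums
    xw = w[:, None] * X
    s2 = np.cumsum(
        (xw[:, :, None] * X[:, None, :])[::-1], 0
    )[::-1]                                           # weighted X X^T sums

    t_vals = time
    i = 0
    while i < n:
        j = i
        while j < n and t_vals[j] == t_vals[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        d = len(d_idx)
        if d > 0:
            wd = w[d_idx]
            xd = X[d_idx]
            sum_wd = wd.sum()
            sum_xd_wd = (wd[:, None] * xd).sum(axis=0)
            sum_xxd_wd = (wd[:, None, None] * xd[:, :, None] * xd[:, None, :]).sum(axis=0)
            ll += eta[d_idx].sum()
            for r in range(d):
                f = r / d
                denom = s0[i] - f * sum_wd
                num1 = s1[i] - f * sum_xd_wd
                num2 = s2[i] - f * sum_xxd_wd
                ll -= math.log(denom)
                grad_term = num1 / denom
                grad -= grad_term
                info += num2 / denom - np.outer(grad_term, grad_term)
            grad += xd.sum(axis=0)
        i = j
    return ll, grad, info


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    subgroup_reference: str | None = None,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton iteration with step-halving.

    Ties are handled with the Efron approximation.  Categorical covariates
    (e.g. molecular subgroup) are dummy-coded against ``subgroup_reference``
    (default: first level alphabetically).  Convergence: relative change in
    the log partial likelihood below ``tol`` (or ``max_iter`` reached, in
    which case the fit is flagged unconverged).  A monotone (separating)
    likelihood is flagged via a diagnostic warning on the returned fit.
    """
    df = cohort.sort_values(duration_col, kind="stable").reset_index(drop=True)
    event = df[event_col].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in cohort")
    time = df[duration_col].to_numpy(dtype=float)
    Xdf = _design_matrix(df, covariates, subgroup_reference)
    names = list(Xdf.columns)
    X = Xdf.to_numpy()
    # center covariates for numerical stability (does not change coef)
    X = X - X.mean(axis=0)
    p = X.shape[1]

    beta = np.zeros(p)
    ll, grad, info = _efron_loglik(beta, X, time, event)
    score_chi2 = float(grad @ np.linalg.solve(info, grad))
    trace = [ll]
    converged = False
    warns: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warns.append("singular information matrix")
            break
        # step-halving: never accept a decrease of the log likelihood
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_grad, new_info = _efron_loglik(new_beta, X, time, event)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            warns.append("step-halving failed to improve the likelihood")
            break
        beta, grad, info = new_beta, new_grad, new_info
        trace.append(new_ll)
        if abs(new_ll - ll) <= tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if np.abs(beta).max() > 20:
        warns.append("possible separation: monotone likelihood (|coef| > 20)")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * norm_dist.sf(np.abs(z))
    return CoxFit(
        covariates=names,
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        p=pvals,
        log_likelihood=float(ll),
        converged=converged,
        n_iter=it,
        ll_trace=trace,
        score_chi2_null=score_chi2,
        warnings=warns,
    )


def score_test_pvalue(fit: CoxFit) -> float:
    """P-value of the score (log-rank-type) test that all coefficients are 0."""
    if fit.score_chi2_null is None:
        raise ValueError("fit carries no score statistic")
    return float(chi2_dist.sf(fit.score_chi2_null, df=len(fit.covariates)))
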