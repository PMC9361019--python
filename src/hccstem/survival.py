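"""Survival stratification by stemness: Kaplan-Meier, log-rank and Cox PH.

Cohorts are stratified at an mRNAsi cutoff (default 0.55, the TCGA
training-cohort median) and compared over a 5-year horizon.  Follow-up
beyond the horizon is administratively censored at the horizon rather
than excluded — excluding longer-lived patients would condition on the
outcome; an exclusion mode exists behind a flag for comparison.

Estimation goes through lifelines (product-limit KM with Greenwood
variance, Efron-tie Cox partial likelihood).  A standalone Cox score
statistic is provided for the classical identity with the log-rank
test at beta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

DEFAULT_CUTOFF = 0.55
DEFAULT_HORIZON = 60.0

__all__ = [
    "DEFAULT_CUTOFF",
    "DEFAULT_HORIZON",
    "KMCurve",
    "CoxFit",
    "stratify_by_cutoff",
    "truncate_followup",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_statistic",
]


@dataclass
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_se: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
                "se": self.greenwood_se,
            }
        )


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: beta, hazard_ratio, ci low/high, wald_p
    converged: bool
    ties_method: str = "efron"

    def beta(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "beta"])

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


def stratify_by_cutoff(scores: pd.Series, cutoff: float = DEFAULT_CUTOFF) -> pd.Series:
    """'high' when the score is strictly greater than the cutoff."""
    return pd.Series(
        np.where(scores.to_numpy(float) > cutoff, "high", "low"),
        index=scores.index,
        name="group",
    )


def truncate_followup(
    records: pd.DataFrame, horizon_months: float = DEFAULT_HORIZON, mode: str = "censor"
) -> pd.DataFrame:
    """Apply the follow-up horizon (default 60 months).

    mode='censor' (default): times beyond the horizon are set to the
    horizon with event = 0.  mode='exclude': drop those records
    entirely (kept for comparison; induces outcome-dependent selection).
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    out = records.copy()
    beyond = out["time_months"] > horizon_months
    if mode == "censor":
        out.loc[beyond, "event"] = 0
        out.loc[beyond, "time_months"] = horizon_months
    elif mode == "exclude":
        out = out[~beyond].copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""
    if len(records) == 0:
        raise ValueError("no records")
    t = records["time_months"].to_numpy(float)
    e = records["event"].to_numpy(int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.sort(np.unique(t[e == 1]))
    if len(event_times) == 0:
        return KMCurve(
            event_times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([]),
            events=np.array([]),
            greenwood_se=np.array([]),
        )
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    tbl = kmf.event_table
    at_risk = tbl.loc[event_times, "at_risk"].to_numpy(float)
    events = tbl.loc[event_times, "observed"].to_numpy(float)
    # Greenwood: var(S(t)) = S(t)^2 * sum_{t_j <= t} d_j / (n_j (n_j - d_j))
    d_all = tbl["observed"].to_numpy(float)
    n_all = tbl["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_all > d_all, d_all / (n_all * (n_all - d_all)), np.inf)
    cum = np.cumsum(terms)
    cum_at = np.array([cum[np.searchsorted(tbl.index.to_numpy(), ti, side="right") - 1] for ti in event_times])
    se = surv * np.sqrt(np.where(np.isfinite(cum_at), cum_at, 0.0))
    return KMCurve(event_times, surv, at_risk, events, se)


def logrank_test(records: pd.DataFrame, group: pd.Series | str = "group") -> tuple[float, float]:
    """Two-group log-rank chi-square (df=1) and p-value."""
    g = records[group] if isinstance(group, str) else group.reindex(records.index)
    if g.nunique() < 2:
        raise ValueError("log-rank needs two groups")
    res = multivariate_logrank_test(
        records["time_months"], g, records["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def _efron_derivatives(
    beta: np.ndarray, X: np.ndarray, t: np.ndarray, e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the Efron-tie Cox partial log-likelihood."""
    p = X.shape[1]
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    eta = X @ beta
    w = np.exp(eta - eta.max())
    for tt in np.unique(t[e == 1]):
        D = (t == tt) & (e == 1)
        R = t >= tt
        d = int(D.sum())
        sR, sD = w[R].sum(), w[D].sum()
        xR = X[R].T @ w[R]
        xD = X[D].T @ w[D]
        qR = (X[R].T * w[R]) @ X[R]
        qD = (X[D].T * w[D]) @ X[D]
        grad += X[D].sum(axis=0)
        for l in range(d):
            f = l / d
            s = sR - f * sD
            xbar = (xR - f * xD) / s
            grad -= xbar
            hess -= (qR - f * qD) / s - np.outer(xbar, xbar)
    return grad, hess


def cox_fit(
    records: pd.DataFrame, covariates: list[str], ties: str = "efron", tol: float = 1e-8
) -> CoxFit:
    """Cox proportional-hazards fit: Newton-Raphson on the Efron-tie
    partial likelihood, with Wald CIs and p-values.

    The initial solve goes through lifelines; the solution is then
    Newton-polished on the exact Efron score until the gradient
    inf-norm falls below ``tol``.
    """
    for c in covariates:
        if records[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    n_events = int(records["event"].sum())
    if n_events < len(covariates):
        raise ValueError("fewer events than covariates")
    df = records[["time_months", "event", *covariates]].copy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_months", event_col="event")
    beta = cph.summary["coef"].to_numpy(float)

    X = df[covariates].to_numpy(float)
    t = df["time_months"].to_numpy(float)
    e = df["event"].to_numpy(int)
    converged = False
    for _ in range(50):
        grad, hess = _efron_derivatives(beta, X, t, e)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            beta = beta - np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information matrix for {covariates}") from exc
    if not converged:
        raise RuntimeError(
            f"Cox fit did not converge (gradient inf-norm {np.max(np.abs(grad)):.3g}); "
            "check for monotone likelihood / separation"
        )
    _, hess = _efron_derivatives(beta, X, t, e)
    se = np.sqrt(np.diag(np.linalg.inv(-hess)))
    z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "hazard_ratio": np.exp(beta),
            "ci95_low": np.exp(beta - 1.959963984540054 * se),
            "ci95_high": np.exp(beta + 1.959963984540054 * se),
            "wald_p": wald_p,
        },
        index=pd.Index(covariates, name="covariate"),
    )
    return CoxFit(summary=summary, converged=True, ties_method=ties)


def cox_score_statistic(records: pd.DataFrame, covariate: str) -> float:
    """Score test statistic U^2/I at beta = 0 for one covariate
    (Cox partial likelihood, Breslow/hypothesis of no ties).

    With a single binary covariate and no tied event times this equals
    the log-rank chi-square exactly.
    """
    t = records["time_months"].to_numpy(float)
    e = records["event"].to_numpy(int)
    x = records[covariate].to_numpy(float)
    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    n = len(t)
    U = 0.0
    I = 0.0
    for i in range(n):
        if e[i] != 1:
            continue
        risk = t >= t[i]
        xr = x[risk]
        xbar = xr.mean()
        U += x[i] - xbar
        I += ((xr - xbar) ** 2).mean()
    if I <= 0:
        raise ValueError("zero information; covariate constant in risk sets")
    return float(U * U / I)
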