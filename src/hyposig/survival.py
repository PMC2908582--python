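"""Kaplan-Meier estimation, log-rank testing and Cox regression.

All three are implemented directly from their defining formulas so that
the estimators can be verified against hand tabulations and brute-force
partial-likelihood maximization:

* Kaplan-Meier: product-limit estimator S(t) = prod (1 - d_k / n_k).
* Log-rank: observed-minus-expected statistic with hypergeometric
  variance summed over distinct event times, chi-squared with 1 df.
* Cox proportional hazards: Newton-Raphson maximization of the partial
  likelihood with the Efron tie correction (Breslow available), standard
  errors from the inverse observed information, Wald two-sided p-values,
  HR = exp(beta), 95% CI = exp(beta +/- 1.96 se).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable
from .stratify import ClusterAssignment

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_log_partial_likelihood",
    "survival_report",
]


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    final_rate: float  # estimate at the largest observed time

    def __post_init__(self) -> None:
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival estimates must be non-increasing")
        if (np.diff(self.at_risk) > 0).any():
            raise ValueError("at-risk counts must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function value of the estimator at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n: int
    n_events: int
    log_likelihood: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def as_frame(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "HR": self.hr,
                "ci_lower": ci[:, 0],
                "ci_upper": ci[:, 1],
                "p": self.wald_p,
            },
            index=self.covariates,
        )


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit estimator; censored-only input gives a flat curve at 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    n = times.size
    at_risk, d, surv = [], [], []
    s = 1.0
    for t in event_times:
        r = int((t_sorted >= t).sum())
        dk = int(((t_sorted == t) & (e_sorted == 1)).sum())
        s *= 1.0 - dk / r
        at_risk.append(r)
        d.append(dk)
        surv.append(s)
    if event_times.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]), np.array([]), 1.0)
    curve = KMCurve(event_times, np.array(at_risk), np.array(d), np.array(surv), surv[-1])
    # estimate at the largest observed time (event or censoring)
    curve.final_rate = curve.survival_at(float(times.max()))
    return curve


def logrank_test(group1, group2) -> LogRankResult:
    """Two-group log-rank test; invariant to swapping the groups."""
    t1, e1 = (np.asarray(a) for a in group1)
    t2, e2 = (np.asarray(a) for a in group2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("log-rank undefined without events")
    times = np.concatenate([t1, t2]).astype(float)
    events = np.concatenate([e1, e2]).astype(int)
    group = np.concatenate([np.ones(t1.size, dtype=int), np.zeros(t2.size, dtype=int)])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at = times >= t
        nk = int(at.sum())
        n1k = int((at & (group == 1)).sum())
        dk = int(((times == t) & (events == 1)).sum())
        d1k = int(((times == t) & (events == 1) & (group == 1)).sum())
        o_minus_e += d1k - dk * n1k / nk
        if nk > 1:
            var += dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
    if var == 0:
        return LogRankResult(0.0, 1.0, t1.size, t2.size)
    chi2 = o_minus_e**2 / var
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, 1)), t1.size, t2.size)


def _cox_groups(times: np.ndarray, events: np.ndarray):
    """Distinct event times with death index sets, on sorted input."""
    out = []
    for t in np.unique(times[events == 1]):
        deaths = np.flatnonzero((times == t) & (events == 1))
        risk = np.flatnonzero(times >= t)
        out.append((deaths, risk))
    return out


def cox_log_partial_likelihood(
    beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray, ties: str = "efron"
) -> float:
    """Log partial likelihood (Efron or Breslow handling of ties)."""
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for deaths, risk in _cox_groups(times, events):
        d = len(deaths)
        s_risk = w[risk].sum()
        s_death = w[deaths].sum()
        ll += eta[deaths].sum()
        if ties == "efron":
            for l in range(d):
                ll -= np.log(s_risk - (l / d) * s_death)
        elif ties == "breslow":
            ll -= d * np.log(s_risk)
        else:
            raise ValueError("ties must be 'efron' or 'breslow'")
    return float(ll)


def _cox_derivatives(beta, X, times, events, ties):
    n, m = X.shape
    eta = X @ beta
    w = np.exp(eta)
    grad = np.zeros(m)
    info = np.zeros((m, m))
    ll = 0.0
    for deaths, risk in _cox_groups(times, events):
        d = len(deaths)
        Xr, wr = X[risk], w[risk]
        s0_r = wr.sum()
        s1_r = wr @ Xr
        s2_r = (wr[:, None] * Xr).T @ Xr
        Xd, wd = X[deaths], w[deaths]
        s0_d = wd.sum()
        s1_d = wd @ Xd
        s2_d = (wd[:, None] * Xd).T @ Xd
        ll += eta[deaths].sum()
        grad += Xd.sum(axis=0)
        for l in range(d):
            f = (l / d) if ties == "efron" else 0.0
            s0 = s0_r - f * s0_d
            s1 = s1_r - f * s1_d
            s2 = s2_r - f * s2_d
            ll -= np.log(s0)
            grad -= s1 / s0
            info += s2 / s0 - np.outer(s1, s1) / s0**2
    return ll, grad, info


def cox_fit(
    covariates: np.ndarray | pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson Cox proportional-hazards fit with step-halving.

    Convergence when max |delta beta| < ``tol``; monotone likelihood
    (perfect separation) or a singular information matrix raises with
    the last iterate attached.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, m = X.shape
    n_events = int(events.sum())
    if m < 1:
        raise ValueError("need at least one covariate")
    if n_events == 0:
        raise ValueError("no events: partial likelihood undefined")
    if n_events < m:
        warnings.warn(f"only {n_events} events for {m} covariates: fit may be singular")
    if (np.ptp(X, axis=0) == 0).any():
        const = [names[j] for j in range(m) if np.ptp(X[:, j]) == 0]
        raise ValueError(f"constant covariates carry no information: {const}")

    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]

    beta = np.zeros(m)
    ll, grad, info = _cox_derivatives(beta, Xs, ts, es, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information matrix at beta={beta}") from exc
        # step-halving keeps the log partial likelihood non-decreasing
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new = cox_log_partial_likelihood(cand, Xs, ts, es, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            raise RuntimeError(f"step-halving failed at beta={beta}")
        delta = np.max(np.abs(cand - beta))
        beta, ll = cand, ll_new
        ll, grad, info = _cox_derivatives(beta, Xs, ts, es, ties)
        if np.max(np.abs(beta)) > 50:
            raise RuntimeError(
                f"monotone likelihood (perfect separation?); last iterate beta={beta}"
            )
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations; beta={beta}")
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(names, beta, se, converged, n, n_events, ll)


def survival_report(
    cohorts: ClinicalTable | dict[str, ClinicalTable],
    assignment: ClusterAssignment,
    ties: str = "efron",
    horizon: float | None = None,
) -> dict:
    """Arm-wise KM + log-rank and multivariate Cox, full cohort and
    MYCN-normal subgroup.

    ``cohorts`` maps endpoint name (e.g. "OS", "EFS") to a clinical
    table; a single table is treated as endpoint "OS".  The Cox model
    uses cluster (poor vs good), INSS stage (4 vs not 4), MYCN
    (amplified vs normal) and age (>=1y vs <1y); the MYCN-normal
    subgroup rerun drops the MYCN covariate.

    Arm survival rates are the KM estimates at ``horizon`` years if
    given, else at the largest observed time in the arm.
    """
    if isinstance(cohorts, ClinicalTable):
        cohorts = {"OS": cohorts}
    if assignment.prognosis is None:
        raise ValueError("assignment must carry prognosis labels")
    sizes = assignment.sizes
    if 0 in sizes.values():
        raise ValueError("degenerate stratification: one cluster is empty")

    report: dict = {"cluster_sizes": sizes, "prognosis": assignment.prognosis}
    poor_ids = set(assignment.poor_samples())

    for endpoint, clin in cohorts.items():
        ids = clin.patient_ids
        if set(ids) - set(assignment.sample_ids):
            raise ValueError("assignment does not cover the cohort")
        poor_mask = np.array([pid in poor_ids for pid in ids])
        report[endpoint] = _endpoint_report(clin, poor_mask, include_mycn=True, ties=ties,
                                            horizon=horizon)
        normal_ids = [pid for pid in ids if clin.table.loc[pid, "mycn"] == "normal"]
        sub = clin.subset(normal_ids)
        sub_poor = np.array([pid in poor_ids for pid in normal_ids])
        report[f"{endpoint}_mycn_normal"] = _endpoint_report(
            sub, sub_poor, include_mycn=False, ties=ties, horizon=horizon
        )
    return report


def _endpoint_report(clin: ClinicalTable, poor_mask: np.ndarray, include_mycn: bool,
                     ties: str, horizon: float | None = None) -> dict:
    times, events = clin.times, clin.events
    out: dict = {"n": len(times), "n_events": int(events.sum()),
                 "n_poor": int(poor_mask.sum()), "n_good": int((~poor_mask).sum())}
    if events.sum() == 0:
        out["flag"] = "no events: KM flat, no tests"
        return out
    if poor_mask.all() or (~poor_mask).all():
        out["flag"] = "single-arm stratification: no comparison"
        return out
    km_poor = km_estimate(times[poor_mask], events[poor_mask])
    km_good = km_estimate(times[~poor_mask], events[~poor_mask])
    if horizon is None:
        out["survival_rate_poor"] = km_poor.final_rate
        out["survival_rate_good"] = km_good.final_rate
    else:
        out["survival_rate_poor"] = km_poor.survival_at(horizon)
        out["survival_rate_good"] = km_good.survival_at(horizon)
    lr = logrank_test((times[poor_mask], events[poor_mask]), (times[~poor_mask], events[~poor_mask]))
    out["logrank_chi2"] = lr.chi2
    out["logrank_p"] = lr.p
    cov = clin.covariate_matrix(include_mycn=include_mycn)
    cov.insert(0, "cluster_poor", poor_mask.astype(float))
    try:
        fit = cox_fit(cov, times, events, ties=ties)
        out["cox"] = fit.as_frame().to_dict(orient="index")
    except (RuntimeError, ValueError) as exc:
        out["cox_error"] = str(exc)
    return out
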