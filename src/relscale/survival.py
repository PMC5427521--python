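"""Recovery-time analysis: Kaplan–Meier curves, the logrank test and a
single-binary-covariate Cox proportional-hazards fit.

For duration-of-illness data the "event" is recovery, so a hazard ratio
above 1 means the treated arm recovers *faster*. Records flagged censored
are treated as censored here (risk-set exits without an event), in contrast
to the moment-based modules where the censoring day stands in for the
recovery day.

Kaplan–Meier estimation and the logrank test are delegated to lifelines.
The Cox fit for one binary covariate is implemented directly with a
safeguarded Newton iteration on the partial log-likelihood, because both
Efron and Breslow tie conventions are needed (and are simple to state for a
single covariate); lifelines' Efron-ties fitter serves as an independent
cross-check in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_model import IPDTrial
from .inference import TestResult

__all__ = ["StepSurvival", "CoxFit", "km_estimate", "logrank", "cox_binary",
           "cox_partial_loglik"]


@dataclass(frozen=True)
class StepSurvival:
    """A Kaplan–Meier step function.

    ``times`` are the distinct observed times (events and censorings),
    ``survival`` the product-limit estimate just after each time;
    ``at_risk``/``events``/``censored`` count patients per time.
    ``all_censored`` flags the degenerate case of no events, where the
    estimator stays at 1 with no terminal drop.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(durations, censor_flags=None) -> StepSurvival:
    """Product-limit (Kaplan–Meier) estimate of the survival function.

    Censored observations reduce the risk set without a survival drop. With
    no censoring the estimate equals 1 minus the empirical CDF at every
    event time.
    """
    t = np.asarray(durations, dtype=float)
    if censor_flags is None:
        censor_flags = np.zeros(t.shape, dtype=bool)
    c = np.asarray(censor_flags, dtype=bool)
    observed = ~c
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=observed)
    # lifelines inserts a t=0 anchor row; keep only observed times
    table = kmf.event_table[kmf.event_table.index > 0]
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]]
    return StepSurvival(
        times=times,
        survival=surv.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        all_censored=bool(not observed.any()),
    )


def logrank(ipd: IPDTrial) -> TestResult:
    """Standard (rho = 0) logrank test between the trial's two arms."""
    a, b = ipd.arm_labels
    xa, ca = ipd.arm_durations(a), ipd.arm_censor_flags(a)
    xb, cb = ipd.arm_durations(b), ipd.arm_censor_flags(b)
    if not ((~ca).any() or (~cb).any()):
        raise ValueError("logrank test needs at least one event")
    res = _ll_logrank(xa, xb, event_observed_A=~ca, event_observed_B=~cb)
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=1,
        method="logrank",
    )


@dataclass(frozen=True)
class CoxFit:
    """Result of a single-binary-covariate Cox proportional-hazards fit."""

    log_hr: float
    rr: float
    ci_low: float
    ci_high: float
    se: float
    level: float
    ties: str
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not self.ci_low <= self.rr <= self.ci_high:
            raise ValueError("CI does not bracket the rate ratio")


def cox_partial_loglik(
    beta: float,
    times: np.ndarray,
    events: np.ndarray,
    group: np.ndarray,
    ties: str = "efron",
) -> float:
    """Cox partial log-likelihood for one binary covariate at ``beta``.

    ``group`` is the 0/1 covariate; ``events`` marks observed events. Ties
    are handled by the Efron or Breslow approximation. Exposed publicly so
    the optimum can be verified against direct evaluation.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=float)
    eb = math.exp(beta)
    ll = 0.0
    for t in np.unique(times[events]):
        d_mask = events & (times == t)
        d = int(d_mask.sum())
        d1 = float(group[d_mask].sum())  # events in group 1 at t
        risk = times >= t
        r1 = float(group[risk].sum())
        r0 = float(risk.sum() - r1)
        s_risk = r0 + r1 * eb
        ll += beta * d1
        if ties == "breslow":
            ll -= d * math.log(s_risk)
        elif ties == "efron":
            s_tied = (d - d1) + d1 * eb
            for j in range(d):
                ll -= math.log(s_risk - (j / d) * s_tied)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return ll


def _cox_derivatives(beta, times, events, group, ties):
    """First and second derivative of the partial log-likelihood."""
    eb = math.exp(beta)
    u = 0.0
    i = 0.0
    for t in np.unique(times[events]):
        d_mask = events & (times == t)
        d = int(d_mask.sum())
        d1 = float(group[d_mask].sum())
        risk = times >= t
        r1 = float(group[risk].sum())
        r0 = float(risk.sum() - r1)
        u += d1
        if ties == "breslow":
            for _ in range(d):
                s = r0 + r1 * eb
                m = r1 * eb / s
                u -= m
                i += m * (1 - m)
        else:  # efron
            s_tied1 = d1 * eb
            s_tied = (d - d1) + s_tied1
            for j in range(d):
                s = (r0 + r1 * eb) - (j / d) * s_tied
                num = r1 * eb - (j / d) * s_tied1
                m = num / s
                u -= m
                i += m - m**2
    return u, i


def cox_binary(
    ipd: IPDTrial,
    ties: str = "efron",
    treated_arm: str | None = None,
    level: float = 0.95,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox model with the treated-arm indicator as sole covariate.

    Maximizes the partial likelihood by Newton iteration with step-halving;
    convergence when the relative change in the partial log-likelihood drops
    below ``tol``. The Wald CI is formed on the log scale and exponentiated.
    A monotone likelihood (complete risk-set separation) is reported with
    ``converged=False`` and a diverging, effectively unbounded estimate.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    arms = ipd.arm_labels
    treated = treated_arm if treated_arm is not None else arms[0]
    control = arms[1] if treated == arms[0] else arms[0]
    times = np.array([r.duration for r in ipd.records], dtype=float)
    events = np.array([not r.censored for r in ipd.records], dtype=bool)
    group = np.array([1.0 if r.arm == treated else 0.0 for r in ipd.records])
    if events.sum() < 2:
        raise ValueError("Cox fit needs at least 2 events")

    from scipy import stats

    beta = 0.0
    ll = cox_partial_loglik(beta, times, events, group, ties)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        u, info = _cox_derivatives(beta, times, events, group, ties)
        if info <= 0:
            break
        step = u / info
        new_beta = beta + step
        new_ll = cox_partial_loglik(new_beta, times, events, group, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll = cox_partial_loglik(new_beta, times, events, group, ties)
            halvings += 1
        rel_change = abs(new_ll - ll) / max(1.0, abs(ll))
        beta, ll = new_beta, new_ll
        if rel_change < tol:
            converged = True
            break
    _, info = _cox_derivatives(beta, times, events, group, ties)
    se = math.sqrt(1 / info) if info > 0 else math.inf
    if not converged or abs(beta) > 20:
        # monotone likelihood: report the diverging direction as unbounded
        sign = math.copysign(1.0, beta) if beta != 0 else 1.0
        return CoxFit(
            log_hr=beta,
            rr=math.exp(min(beta, 700)),
            ci_low=0.0 if sign < 0 else math.exp(min(beta - 10, 700)),
            ci_high=math.inf,
            se=se,
            level=level,
            ties=ties,
            iterations=iterations,
            converged=False,
        )
    z = stats.norm.ppf(0.5 + level / 2)
    return CoxFit(
        log_hr=beta,
        rr=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        se=se,
        level=level,
        ties=ties,
        iterations=iterations,
        converged=True,
    )


def cox_score_test_at_null(ipd: IPDTrial, treated_arm: str | None = None,
                           ties: str = "breslow") -> TestResult:
    """Score test of beta = 0 from the Cox partial likelihood.

    On tie-free data with Breslow ties this statistic coincides with the
    logrank chi-square.
    """
    arms = ipd.arm_labels
    treated = treated_arm if treated_arm is not None else arms[0]
    times = np.array([r.duration for r in ipd.records], dtype=float)
    events = np.array([not r.censored for r in ipd.records], dtype=bool)
    group = np.array([1.0 if r.arm == treated else 0.0 for r in ipd.records])
    u, info = _cox_derivatives(0.0, times, events, group, ties)
    from scipy import stats

    chi2 = u**2 / info
    return TestResult(
        statistic=float(chi2),
        p_value=float(stats.chi2.sf(chi2, 1)),
        df=1,
        method=f"cox-score-{ties}",
    )
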