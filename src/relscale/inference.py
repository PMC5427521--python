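"""Hypothesis tests and confidence intervals for two-arm duration data.

The centrepiece is the family of constructions for a confidence interval on
the *relative* treatment effect, i.e. on ``100 * (mean_t / mean_c - 1)``:

``normalized-t``
    The pooled-variance two-sample t interval for the mean difference,
    rescaled by the control mean into percent. Because the %-of-control
    transformation is linear, this interval inherits the t-test of the
    original values exactly.
``log-t`` (IPD only)
    Pooled t interval for the difference of log-transformed durations,
    back-transformed via ``100 * (exp(bound) - 1)``. Log transformation
    tends to equalize arm variances for duration data.
``taylor``
    Delta-method (Taylor-series) interval for the log ratio of means from
    summary statistics: SE(ln RoM) = sqrt(sd_t^2/(n_t mean_t^2) +
    sd_c^2/(n_c mean_c^2)), normal quantiles on the log scale.
``fieller``
    Fieller's interval for the ratio of two normal means, unequal-variance
    form with Satterthwaite degrees of freedom; possibly unbounded when the
    control mean is not significantly different from zero.
``bootstrap`` (IPD only)
    Nonparametric stratified bootstrap with bias-corrected-and-accelerated
    (BCa) endpoints, under either a fixed-denominator "normalized
    difference" scheme or a ratio-of-resampled-means scheme.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .data_model import ArmSummary, IPDTrial, TrialSummary

__all__ = [
    "TestResult",
    "IntervalEstimate",
    "variance_ratio_test",
    "variance_ratio_test_from_moments",
    "two_sample_t",
    "permutation_test",
    "pooled_t_interval",
    "ci_normalized_t",
    "ci_log_t",
    "ci_taylor",
    "ci_fieller",
    "ci_bootstrap",
    "bca_interval",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | tuple[float, float] | None = None
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class IntervalEstimate:
    """A confidence interval on a named scale.

    ``unbounded`` marks Fieller's degenerate cases, where the confidence set
    is the whole line or the complement of an interval rather than a bounded
    interval; the stored ``low``/``high`` then delimit the excluded region
    (or are infinite) and must not be read as ordinary bounds.
    """

    low: float
    high: float
    level: float
    method: str
    scale: str
    unbounded: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not self.unbounded and self.low > self.high:
            raise ValueError(f"low {self.low} > high {self.high}")

    @property
    def width(self) -> float:
        return self.high - self.low


# ---------------------------------------------------------------------------
# tests


def variance_ratio_test_from_moments(
    sd_a: float, n_a: int, sd_b: float, n_b: int
) -> TestResult:
    """F test for equality of two variances from SDs and sample sizes.

    F = (sd_a / sd_b)^2 on (n_a - 1, n_b - 1) degrees of freedom; the
    two-sided p-value is twice the smaller tail probability, capped at 1
    (R's ``var.test`` convention).
    """
    if sd_a == 0 or sd_b == 0:
        raise ValueError("variance ratio test undefined for a zero-SD sample")
    f = (sd_a / sd_b) ** 2
    dfn, dfd = n_a - 1, n_b - 1
    cdf = stats.f.cdf(f, dfn, dfd)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return TestResult(statistic=f, p_value=float(p), df=(dfn, dfd),
                      method="variance-ratio-F")


def variance_ratio_test(a: ArmSummary, b: ArmSummary) -> TestResult:
    """F test comparing two arms' variances; see
    :func:`variance_ratio_test_from_moments`."""
    return variance_ratio_test_from_moments(a.sd, a.n, b.sd, b.n)


def _pooled_sd(a: ArmSummary, b: ArmSummary) -> float:
    return math.sqrt(
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    )


def two_sample_t_from_summaries(
    a: ArmSummary, b: ArmSummary, equal_var: bool = True
) -> TestResult:
    """Two-sample t test (a minus b) from summary statistics."""
    if equal_var:
        sp = _pooled_sd(a, b)
        df = a.n + b.n - 2
        se = sp * math.sqrt(1 / a.n + 1 / b.n)
        method = "pooled-t"
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        method = "welch-t"
    if se == 0:
        # both arms constant: conventionally p = 1 when means agree
        t = 0.0 if a.mean == b.mean else math.inf * math.copysign(1, a.mean - b.mean)
        p = 1.0 if a.mean == b.mean else 0.0
        return TestResult(statistic=t, p_value=p, df=df, method=method)
    t = (a.mean - b.mean) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=t, p_value=float(p), df=df, method=method)


def two_sample_t(x, y, equal_var: bool = True) -> TestResult:
    """Two-sample t test on raw durations (pooled or Welch per ``equal_var``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    from .data_model import summarize_arm

    a = summarize_arm(x, quantile_probs=(), label="x")
    b = summarize_arm(y, quantile_probs=(), label="y")
    return two_sample_t_from_summaries(a, b, equal_var=equal_var)


def permutation_test(
    ipd: IPDTrial,
    max_exact_n: int = 100_000,
    reps: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Two-sample Fisher–Pitman permutation test on the difference in means.

    All re-assignments of arm labels are enumerated exactly when the number
    of distinct assignments ``C(n, n_1)`` does not exceed ``max_exact_n``;
    otherwise a Monte-Carlo approximation with ``reps`` random assignments is
    used (the observed assignment is always counted in the numerator, so the
    Monte-Carlo p-value is never 0).
    """
    arm1, arm2 = ipd.arm_labels
    x = ipd.arm_durations(arm1)
    y = ipd.arm_durations(arm2)
    pooled = np.concatenate([x, y])
    n1 = x.size
    observed = abs(x.mean() - y.mean())
    total = pooled.sum()
    n2 = y.size
    n = n1 + n2

    def stat_from_sum1(s1: float) -> float:
        return abs(s1 / n1 - (total - s1) / n2)

    n_comb = special.comb(n, n1, exact=True)
    tol = 1e-12 * (1 + observed)
    if n_comb <= max_exact_n:
        hits = sum(
            stat_from_sum1(sum(c)) >= observed - tol
            for c in itertools.combinations(pooled, n1)
        )
        return TestResult(
            statistic=float(x.mean() - y.mean()),
            p_value=hits / n_comb,
            method="permutation-exact",
        )
    if reps < 100:
        raise ValueError("Monte-Carlo permutation test needs reps >= 100")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(pooled)
        if stat_from_sum1(perm[:n1].sum()) >= observed - tol:
            hits += 1
    return TestResult(
        statistic=float(x.mean() - y.mean()),
        p_value=(hits + 1) / (reps + 1),
        method="permutation-mc",
    )


# ---------------------------------------------------------------------------
# confidence intervals


def pooled_t_interval(
    a: ArmSummary, b: ArmSummary, level: float = 0.95, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t CI for the mean difference a - b (days)."""
    res = two_sample_t_from_summaries(a, b, equal_var=equal_var)
    if equal_var:
        se = _pooled_sd(a, b) * math.sqrt(1 / a.n + 1 / b.n)
    else:
        se = math.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
    tq = stats.t.ppf(0.5 + level / 2, res.df)
    d = a.mean - b.mean
    return d - tq * se, d + tq * se


def ci_normalized_t(
    trial: TrialSummary, level: float = 0.95, equal_var: bool = True
) -> IntervalEstimate:
    """Pooled-t mean-difference CI rescaled by the control mean into percent.

    This is the %-of-control transformation applied to the ordinary
    absolute-scale interval; it is exactly equivalent to running the t
    interval on data divided by the control mean and multiplied by 100.
    """
    lo, hi = pooled_t_interval(trial.treated, trial.control, level, equal_var)
    c = trial.control.mean
    return IntervalEstimate(
        low=100 * lo / c,
        high=100 * hi / c,
        level=level,
        method="normalized-t" if equal_var else "normalized-welch-t",
        scale="relative-percent",
    )


def ci_log_t(
    ipd: IPDTrial, level: float = 0.95, treated_arm: str | None = None
) -> IntervalEstimate:
    """Pooled-t CI on log durations, back-transformed to relative-effect %."""
    arms = ipd.arm_labels
    treated = treated_arm if treated_arm is not None else arms[0]
    control = arms[1] if treated == arms[0] else arms[0]
    x = ipd.arm_durations(treated)
    y = ipd.arm_durations(control)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-scale CI requires all durations > 0")
    lx, ly = np.log(x), np.log(y)
    nx, ny = lx.size, ly.size
    sp2 = ((nx - 1) * lx.var(ddof=1) + (ny - 1) * ly.var(ddof=1)) / (nx + ny - 2)
    se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    d = lx.mean() - ly.mean()
    tq = stats.t.ppf(0.5 + level / 2, nx + ny - 2)
    return IntervalEstimate(
        low=100 * (math.exp(d - tq * se) - 1),
        high=100 * (math.exp(d + tq * se) - 1),
        level=level,
        method="log-t",
        scale="relative-percent",
    )


def ci_taylor(
    trial: TrialSummary, level: float = 0.95, use_t: bool = False
) -> IntervalEstimate:
    """Delta-method (Taylor-series) CI for the ratio of means, as percent.

    The SE of ln(RoM) is ``sqrt(sd_t^2/(n_t mean_t^2) + sd_c^2/(n_c
    mean_c^2))``; the interval uses normal quantiles on the log scale by
    default (``use_t`` swaps in t quantiles on n_t + n_c - 2 df) and is
    exponentiated back to ``100 * (ratio - 1)`` percent.
    """
    t, c = trial.treated, trial.control
    if t.mean <= 0 or c.mean <= 0:
        raise ValueError("Taylor-series ratio CI requires positive arm means")
    se = math.sqrt(t.sd**2 / (t.n * t.mean**2) + c.sd**2 / (c.n * c.mean**2))
    if use_t:
        q = stats.t.ppf(0.5 + level / 2, t.n + c.n - 2)
    else:
        q = stats.norm.ppf(0.5 + level / 2)
    log_rom = math.log(t.mean / c.mean)
    return IntervalEstimate(
        low=100 * (math.exp(log_rom - q * se) - 1),
        high=100 * (math.exp(log_rom + q * se) - 1),
        level=level,
        method="taylor",
        scale="relative-percent",
    )


def ci_fieller(
    trial: TrialSummary, level: float = 0.95, equal_var: bool = False
) -> IntervalEstimate:
    """Fieller's CI for the ratio of arm means, reported as relative %.

    The confidence set is the set of ratios rho solving
    ``(mean_t - rho * mean_c)^2 <= t^2 (v_t + rho^2 v_c)`` where ``v`` are
    squared standard errors of the arm means. With the unequal-variance form
    (default) the degrees of freedom follow the Satterthwaite approximation
    evaluated at the point-estimate ratio. When the control mean is not
    significantly nonzero at the requested level, the set is unbounded; the
    result is then flagged instead of being truncated.
    """
    t, c = trial.treated, trial.control
    r = t.mean / c.mean
    if equal_var:
        sp2 = _pooled_sd(t, c) ** 2
        v_t, v_c = sp2 / t.n, sp2 / c.n
        df = t.n + c.n - 2
    else:
        v_t, v_c = t.sd**2 / t.n, c.sd**2 / c.n
        df = (v_t + r**2 * v_c) ** 2 / (
            v_t**2 / (t.n - 1) + (r**2 * v_c) ** 2 / (c.n - 1)
        )
    tq = stats.t.ppf(0.5 + level / 2, df)
    t2 = tq**2
    # quadratic in rho: A rho^2 - 2 B rho + C <= 0
    a_coef = c.mean**2 - t2 * v_c
    b_coef = t.mean * c.mean
    c_coef = t.mean**2 - t2 * v_t
    disc = b_coef**2 - a_coef * c_coef
    method = "fieller" if not equal_var else "fieller-pooled"
    if a_coef > 0 and disc >= 0:
        root = math.sqrt(disc)
        lo = (b_coef - root) / a_coef
        hi = (b_coef + root) / a_coef
        return IntervalEstimate(
            low=100 * (lo - 1),
            high=100 * (hi - 1),
            level=level,
            method=method,
            scale="relative-percent",
        )
    if a_coef <= 0 and disc >= 0:
        # exclusive case: confidence set is the complement of (lo, hi)
        root = math.sqrt(disc)
        lo = (b_coef + root) / a_coef
        hi = (b_coef - root) / a_coef
        return IntervalEstimate(
            low=100 * (lo - 1),
            high=100 * (hi - 1),
            level=level,
            method=method,
            scale="relative-percent",
            unbounded=True,
        )
    # disc < 0: whole real line
    return IntervalEstimate(
        low=-math.inf,
        high=math.inf,
        level=level,
        method=method,
        scale="relative-percent",
        unbounded=True,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bca_interval(
    theta_hat: float,
    boot: np.ndarray,
    jack: np.ndarray,
    level: float,
) -> tuple[float, float]:
    """Bias-corrected-and-accelerated percentile endpoints.

    ``boot`` are bootstrap replicates of the statistic, ``jack`` its
    leave-one-out (jackknife) values used for the acceleration constant.
    Degenerate resampling distributions (all replicates equal) collapse to a
    zero-width interval at the point estimate.
    """
    boot = np.asarray(boot, dtype=float)
    if np.allclose(boot, boot[0]):
        return theta_hat, theta_hat
    # bias correction from the proportion of replicates below the estimate
    prop = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    prop = min(max(prop, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1.0))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    acc = num / den if den > 0 else 0.0
    alpha = (1 - level) / 2
    za, zb = stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)
    lo_p = stats.norm.cdf(z0 + (z0 + za) / (1 - acc * (z0 + za)))
    hi_p = stats.norm.cdf(z0 + (z0 + zb) / (1 - acc * (z0 + zb)))
    lo, hi = np.quantile(boot, [lo_p, hi_p])
    return float(lo), float(hi)


def _bootstrap_relative(
    x: np.ndarray,
    y: np.ndarray,
    scheme: str,
    reps: int,
    rng: np.random.Generator,
    level: float,
) -> tuple[float, float, float]:
    """Core stratified BCa bootstrap of the relative effect; returns
    (theta_hat, low, high) in percent."""
    nx, ny = x.size, y.size
    y_mean_obs = y.mean()

    if scheme == "normalized-difference":
        # data are pre-normalized to % of the observed control mean; the
        # statistic is the plain difference of resampled arm means
        xp = 100 * x / y_mean_obs
        yp = 100 * y / y_mean_obs

        def stat(mx: np.ndarray, my: np.ndarray) -> np.ndarray:
            return mx - my

        bx = xp[rng.integers(0, nx, size=(reps, nx))].mean(axis=1)
        by = yp[rng.integers(0, ny, size=(reps, ny))].mean(axis=1)
        theta = float(xp.mean() - yp.mean())
        boot = stat(bx, by)
        # jackknife over the pooled sample, leave-one-out within its arm
        jack_x = (xp.sum() - xp) / (nx - 1) - yp.mean()
        jack_y = xp.mean() - (yp.sum() - yp) / (ny - 1)
    elif scheme == "ratio":
        bx = x[rng.integers(0, nx, size=(reps, nx))].mean(axis=1)
        by = y[rng.integers(0, ny, size=(reps, ny))].mean(axis=1)
        theta = float(100 * (x.mean() / y_mean_obs - 1))
        boot = 100 * (bx / by - 1)
        jack_x = 100 * (((x.sum() - x) / (nx - 1)) / y_mean_obs - 1)
        jack_y = 100 * (x.mean() / ((y.sum() - y) / (ny - 1)) - 1)
    else:
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")

    jack = np.concatenate([jack_x, jack_y])
    lo, hi = bca_interval(theta, boot, jack, level)
    return theta, lo, hi


def ci_bootstrap(
    ipd: IPDTrial,
    scheme: str = "ratio",
    reps: int = 9999,
    seed: int | None = None,
    level: float = 0.95,
    treated_arm: str | None = None,
) -> IntervalEstimate:
    """Stratified nonparametric BCa bootstrap CI for the relative effect (%).

    ``scheme="normalized-difference"`` resamples means of data pre-scaled to
    % of the observed control mean (fixed denominator); ``scheme="ratio"``
    resamples the ratio of arm means directly. Patients are resampled within
    their own arm. Reproducible given ``seed``.
    """
    if reps < 999:
        raise ValueError("bootstrap needs reps >= 999")
    arms = ipd.arm_labels
    treated = treated_arm if treated_arm is not None else arms[0]
    control = arms[1] if treated == arms[0] else arms[0]
    x = ipd.arm_durations(treated)
    y = ipd.arm_durations(control)
    rng = np.random.default_rng(seed)
    _, lo, hi = _bootstrap_relative(x, y, scheme, reps, rng, level)
    return IntervalEstimate(
        low=lo,
        high=hi,
        level=level,
        method=f"bootstrap-bca-{scheme}",
        scale="relative-percent",
    )
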