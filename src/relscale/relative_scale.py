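"""Effect estimation on absolute, relative (%-of-control) and SMD scales.

The %-of-control transformation divides both arms' means and SDs by the
control mean and multiplies by 100, so that the control mean becomes 100 %
exactly and the treated mean becomes the ratio of means (RoM) in percent.
Because the transformation is linear, the two-sample t statistic on the
transformed values is identical to the t statistic on the original days
scale; the transformation changes the units of the report, not the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .data_model import IPDTrial, TrialSummary
from . import inference
from .inference import pooled_t_interval

__all__ = [
    "EffectEstimate",
    "RelativeTrialSummary",
    "to_relative",
    "effect_absolute",
    "effect_relative",
    "effect_smd",
    "RELATIVE_CI_METHODS",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A point effect on a named scale with its confidence interval.

    ``scale`` is one of ``absolute-days`` (mean difference in days),
    ``relative-percent`` (% change of the control mean), ``rom-ratio``
    (ratio of means) or ``smd`` (standardized mean difference).
    """

    scale: str
    point: float
    ci_low: float
    ci_high: float
    level: float
    method: str
    unbounded: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not self.unbounded and math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if not self.ci_low <= self.ci_high:
                raise ValueError("ci_low must not exceed ci_high")


@dataclass(frozen=True)
class RelativeTrialSummary:
    """A trial's summary statistics on the %-of-control scale."""

    label: str
    treated_mean_pct: float
    treated_sd_pct: float
    control_mean_pct: float
    control_sd_pct: float
    n_treated: int
    n_control: int

    def __post_init__(self) -> None:
        if self.control_mean_pct != 100.0:
            raise ValueError("control mean must be exactly 100 on the %-scale")


def to_relative(trial: TrialSummary) -> RelativeTrialSummary:
    """Transform a trial's means and SDs to the %-of-control scale.

    Each arm's mean and SD are divided by the control mean and multiplied by
    100; sample sizes are unchanged. The ratio SD/mean within each arm is
    preserved exactly.
    """
    c = trial.control.mean
    if c <= 0:
        raise ValueError("control mean must be > 0")
    return RelativeTrialSummary(
        label=trial.label,
        treated_mean_pct=100 * trial.treated.mean / c,
        treated_sd_pct=100 * trial.treated.sd / c,
        control_mean_pct=100.0,
        control_sd_pct=100 * trial.control.sd / c,
        n_treated=trial.treated.n,
        n_control=trial.control.n,
    )


def effect_absolute(
    trial: TrialSummary, level: float = 0.95, equal_var: bool = True
) -> EffectEstimate:
    """Mean difference (treated - control) in days with its two-sample t CI.

    The interval is the pooled-variance t interval by default; pass
    ``equal_var=False`` for the Welch form.
    """
    lo, hi = pooled_t_interval(trial.treated, trial.control, level, equal_var)
    return EffectEstimate(
        scale="absolute-days",
        point=trial.treated.mean - trial.control.mean,
        ci_low=lo,
        ci_high=hi,
        level=level,
        method="pooled-t" if equal_var else "welch-t",
    )


RELATIVE_CI_METHODS = ("normalized-t", "log-t", "taylor", "fieller", "bootstrap")

_SUMMARY_ONLY = {"normalized-t", "taylor", "fieller"}
_IPD_ONLY = {"log-t", "bootstrap"}


def effect_relative(
    trial: TrialSummary,
    level: float = 0.95,
    method: str = "normalized-t",
    ipd: IPDTrial | None = None,
    **kwargs,
) -> EffectEstimate:
    """Relative effect ``100 * (mean_t/mean_c - 1)`` in % with a CI.

    ``method`` selects the interval construction; ``log-t`` and
    ``bootstrap`` require individual patient data via ``ipd`` (extra
    keyword arguments such as ``scheme``, ``reps`` and ``seed`` are passed
    through to the bootstrap).
    """
    if method not in RELATIVE_CI_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {RELATIVE_CI_METHODS}")
    if method in _IPD_ONLY and ipd is None:
        raise TypeError(f"method {method!r} requires individual patient data (ipd=)")
    point = 100 * (trial.treated.mean / trial.control.mean - 1)
    if method == "normalized-t":
        iv = inference.ci_normalized_t(trial, level, **kwargs)
    elif method == "taylor":
        iv = inference.ci_taylor(trial, level, **kwargs)
    elif method == "fieller":
        iv = inference.ci_fieller(trial, level, **kwargs)
    elif method == "log-t":
        iv = inference.ci_log_t(ipd, level, **kwargs)
    else:  # bootstrap
        iv = inference.ci_bootstrap(ipd, level=level, **kwargs)
    return EffectEstimate(
        scale="relative-percent",
        point=point,
        ci_low=iv.low,
        ci_high=iv.high,
        level=level,
        method=iv.method,
        unbounded=iv.unbounded,
    )


def _hedges_correction(df: int) -> float:
    """Exact small-sample correction factor J = Gamma(df/2) / ... for Hedges' g."""
    return math.exp(
        math.lgamma(df / 2) - math.log(math.sqrt(df / 2)) - math.lgamma((df - 1) / 2)
    )


def effect_smd(
    trial: TrialSummary, level: float = 0.95, flavor: str = "hedges"
) -> EffectEstimate:
    """Standardized mean difference (treated - control) / pooled SD.

    Hedges' g (small-sample corrected) by default; ``flavor="cohen"`` gives
    the uncorrected Cohen's d. The CI uses the standard normal approximation
    with the usual large-sample variance of the SMD.
    """
    t, c = trial.treated, trial.control
    df = t.n + c.n - 2
    sp2 = ((t.n - 1) * t.sd**2 + (c.n - 1) * c.sd**2) / df
    if sp2 <= 0:
        raise ValueError("pooled SD must be positive for an SMD")
    d = (t.mean - c.mean) / math.sqrt(sp2)
    if flavor == "hedges":
        j = _hedges_correction(df)
        point = j * d
        var = j**2 * ((t.n + c.n) / (t.n * c.n) + d**2 / (2 * (t.n + c.n)))
        method = "hedges-g"
    elif flavor == "cohen":
        point = d
        var = (t.n + c.n) / (t.n * c.n) + d**2 / (2 * (t.n + c.n))
        method = "cohen-d"
    else:
        raise ValueError(f"unknown SMD flavor {flavor!r}")
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(var)
    return EffectEstimate(
        scale="smd",
        point=point,
        ci_low=point - z * se,
        ci_high=point + z * se,
        level=level,
        method=method,
    )
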