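"""Inverse-variance pooling with heterogeneity statistics, and the
side-by-side comparison of scales it enables.

Pooling the same set of trials on different effect scales (mean difference
in days, % of the control mean, SMD) generally yields different amounts of
between-study heterogeneity; the scale with lower Q / I-squared captures the
treatment effect in a more transportable way. ``scale_comparison`` runs the
same trials through all three scales and reports the heterogeneity
statistics side by side.

Fixed-effect weights are 1/se^2; the random-effects model uses the
DerSimonian–Laird moment estimate of the between-study variance tau^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TrialSummary
from .relative_scale import effect_absolute, effect_smd

__all__ = ["StudyEffect", "PooledResult", "pool", "scale_comparison"]


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect estimate: point, standard error, scale tag."""

    label: str
    point: float
    se: float
    scale: str

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.label!r}: se must be > 0")


@dataclass(frozen=True)
class PooledResult:
    """An inverse-variance pooled effect with heterogeneity statistics."""

    point: float
    ci_low: float
    ci_high: float
    se: float
    z: float
    p_value: float
    q: float
    df: int
    i2: float  # percent
    tau2: float
    het_p: float
    model: str
    level: float
    scale: str
    weights: pd.DataFrame  # per-study label, weight %


def pool(
    effects: list[StudyEffect], model: str = "fixed", level: float = 0.95
) -> PooledResult:
    """Inverse-variance pooling of study effects on a common scale.

    Fixed-effect: weights ``1/se^2``. Random-effects: DerSimonian–Laird
    ``tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))`` with weights
    ``1/(se^2 + tau^2)``. Cochran's Q and ``I^2 = max(0, (Q - df)/Q) * 100``
    are always computed from the fixed-effect weights; the heterogeneity
    p-value is the chi-square tail of Q on df = k - 1.
    """
    if not effects:
        raise ValueError("need at least one study")
    scales = {e.scale for e in effects}
    if len(scales) != 1:
        raise ValueError(f"all studies must share one scale, got {sorted(scales)}")
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    x = np.array([e.point for e in effects])
    se = np.array([e.se for e in effects])
    w = 1 / se**2
    mu_fixed = np.sum(w * x) / np.sum(w)
    df = len(effects) - 1
    q = float(np.sum(w * (x - mu_fixed) ** 2))
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    het_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    tau2 = 0.0
    if model == "random" and df > 0:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_used = 1 / (se**2 + tau2) if model == "random" else w
    mu = float(np.sum(w_used * x) / np.sum(w_used))
    se_mu = float(math.sqrt(1 / np.sum(w_used)))
    z = mu / se_mu
    zq = stats.norm.ppf(0.5 + level / 2)
    weights = pd.DataFrame(
        {
            "label": [e.label for e in effects],
            "point": x,
            "se": se,
            "weight_pct": 100 * w_used / np.sum(w_used),
        }
    )
    return PooledResult(
        point=mu,
        ci_low=mu - zq * se_mu,
        ci_high=mu + zq * se_mu,
        se=se_mu,
        z=float(z),
        p_value=float(2 * stats.norm.sf(abs(z))),
        q=q,
        df=df,
        i2=float(i2),
        tau2=float(tau2),
        het_p=het_p,
        model=model,
        level=level,
        scale=effects[0].scale,
        weights=weights,
    )


def _study_effects(trial: TrialSummary) -> dict[str, StudyEffect]:
    """Per-trial effects on the three scales with their standard errors.

    The relative-% standard error is the pooled-t SE of the mean difference
    divided by the control mean and multiplied by 100 — the %-of-control
    transformation applied to the absolute-scale SE.
    """
    t, c = trial.treated, trial.control
    sp = math.sqrt(((t.n - 1) * t.sd**2 + (c.n - 1) * c.sd**2) / (t.n + c.n - 2))
    se_md = sp * math.sqrt(1 / t.n + 1 / c.n)
    md = effect_absolute(trial)
    smd = effect_smd(trial)
    z = stats.norm.ppf(0.975)
    se_smd = (smd.ci_high - smd.ci_low) / (2 * z)
    return {
        "absolute-days": StudyEffect(trial.label, md.point, se_md, "absolute-days"),
        "relative-percent": StudyEffect(
            trial.label, 100 * (t.mean / c.mean - 1), 100 * se_md / c.mean,
            "relative-percent",
        ),
        "smd": StudyEffect(trial.label, smd.point, se_smd, "smd"),
    }


def scale_comparison(
    trials: list[TrialSummary], model: str = "fixed", level: float = 0.95
) -> dict[str, PooledResult]:
    """Pool the same trials on each scale and report heterogeneity side by side.

    Returns a map from scale tag (``absolute-days``, ``relative-percent``,
    ``smd``) to the pooled result on that scale.
    """
    if len(trials) < 2:
        raise ValueError("scale comparison needs at least 2 trials")
    per_scale: dict[str, list[StudyEffect]] = {}
    for trial in trials:
        for scale, eff in _study_effects(trial).items():
            per_scale.setdefault(scale, []).append(eff)
    return {
        scale: pool(effs, model=model, level=level)
        for scale, effs in per_scale.items()
    }
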