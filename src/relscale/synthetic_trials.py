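"""Synthetic two-arm duration trials with known generative structure.

Real cold-duration data are integer days, right-skewed, roughly uniform to
gamma-shaped, and occasionally right-censored. The generator draws a control
arm from a chosen baseline family and produces the treated arm under either
a *multiplicative* model (every duration scaled by a ratio in (0, 1]) or an
*additive* model (every duration shortened by a fixed number of days). The
additive model can push draws to zero or below; such draws are resampled,
with the resample count recorded, because real durations cannot be
non-positive — the very tension the scale diagnostics are designed to
expose.

``trial_like`` produces integer-day trials whose arm sizes, means and SDs
match the two packaged zinc-lozenge trials (within 5 % of the published
values), including the published censoring pattern for the 1996 trial, so
that IPD-level operations can be exercised on realistic reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import DurationRecord, IPDTrial
from .datasets import MOSSAD, PETRUS

__all__ = ["TrialConfig", "SimulatedTrial", "simulate_trial", "trial_like"]


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of a synthetic trial.

    Parameters
    ----------
    baseline : str
        Control-arm family: ``lognormal``, ``gamma`` or
        ``discrete-uniform-days``.
    baseline_mean, baseline_sd : float
        Target mean and SD of the control distribution, in days.
    effect : str
        ``multiplicative`` (treated = control draw x ``ratio``) or
        ``additive`` (treated = control draw - ``shift_days``).
    ratio : float
        Multiplicative ratio in (0, 1]; 1.0 is the null.
    shift_days : float
        Additive shortening in days (used when ``effect="additive"``).
    n_treated, n_control : int
        Arm sizes; at least 2 each.
    censor_fraction : float
        Fraction of each arm to censor, in [0, 1).
    censor_mechanism : str
        ``administrative-day`` (censor everything beyond a cut day) or
        ``random-uniform`` (censoring day uniform on (0, duration)).
    round_days : bool
        Round durations to whole days (half-up, floor 1), mimicking daily
        symptom diaries.
    seed : int or None
        Seed for the trial's random generator.
    """

    baseline: str = "lognormal"
    baseline_mean: float = 7.0
    baseline_sd: float = 3.5
    effect: str = "multiplicative"
    ratio: float = 0.75
    shift_days: float = 2.0
    n_treated: int = 50
    n_control: int = 50
    censor_fraction: float = 0.0
    censor_mechanism: str = "administrative-day"
    round_days: bool = False
    seed: int | None = None
    treated_label: str = "treated"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if self.baseline not in ("lognormal", "gamma", "discrete-uniform-days"):
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if self.effect not in ("multiplicative", "additive"):
            raise ValueError(f"unknown effect model {self.effect!r}")
        if not 0 < self.ratio <= 1:
            raise ValueError("ratio must be in (0, 1]")
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("need n >= 2 per arm")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimulatedTrial:
    """A simulated trial plus generation diagnostics."""

    ipd: IPDTrial
    resampled_treated: int = 0
    high_resample_warning: bool = False


def _draw_baseline(cfg: TrialConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    m, s = cfg.baseline_mean, cfg.baseline_sd
    if cfg.baseline == "lognormal":
        sigma2 = math.log(1 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    if cfg.baseline == "gamma":
        shape = (m / s) ** 2
        scale = s**2 / m
        return rng.gamma(shape, scale, size=n)
    # discrete uniform on integer days with approximately matching moments:
    # uniform on {a..b} has mean (a+b)/2 and sd sqrt(((b-a+1)^2 - 1)/12)
    half_range = math.sqrt(3.0) * s
    a = max(1, int(round(m - half_range)))
    b = max(a + 1, int(round(m + half_range)))
    return rng.integers(a, b + 1, size=n).astype(float)


def _round_days(x: np.ndarray) -> np.ndarray:
    """Round half-up to whole days with a floor of 1 day."""
    return np.maximum(1.0, np.floor(x + 0.5))


def simulate_trial(config: TrialConfig) -> SimulatedTrial:
    """Simulate an IPD trial under ``config``; reproducible given its seed.

    Under the additive model, treated draws that land at or below zero are
    resampled until positive; the count is returned, and a warning flag is
    set when more than 10 % of the treated arm needed resampling (an
    additive effect that collides this often with the support of the data is
    itself diagnostic).
    """
    rng = np.random.default_rng(config.seed)
    control = _draw_baseline(config, config.n_control, rng)
    treated_base = _draw_baseline(config, config.n_treated, rng)
    resampled = 0
    if config.effect == "multiplicative":
        treated = treated_base * config.ratio
    else:
        treated = treated_base - config.shift_days
        bad = treated <= 0
        while bad.any():
            resampled += int(bad.sum())
            redraw = _draw_baseline(config, int(bad.sum()), rng) - config.shift_days
            treated[bad] = redraw
            bad = treated <= 0
    if config.round_days:
        control = _round_days(control)
        treated = _round_days(treated)

    def censor(durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flags = np.zeros(durations.size, dtype=bool)
        if config.censor_fraction > 0:
            k = int(round(config.censor_fraction * durations.size))
            if k > 0:
                if config.censor_mechanism == "administrative-day":
                    # censor the k longest durations at the k-th largest value
                    order = np.argsort(durations)
                    cut_idx = order[-k:]
                    cut_day = durations[order[-k]]
                    durations = durations.copy()
                    durations[cut_idx] = cut_day
                    flags[cut_idx] = True
                elif config.censor_mechanism == "random-uniform":
                    idx = rng.choice(durations.size, size=k, replace=False)
                    durations = durations.copy()
                    u = rng.uniform(0.2, 1.0, size=k)
                    durations[idx] = np.maximum(
                        1.0 if config.round_days else 1e-3, durations[idx] * u
                    )
                    if config.round_days:
                        durations[idx] = _round_days(durations[idx])
                    flags[idx] = True
                else:
                    raise ValueError(
                        f"unknown censoring mechanism {config.censor_mechanism!r}"
                    )
        return durations, flags

    treated, tflags = censor(treated)
    control, cflags = censor(control)
    records = [
        DurationRecord(duration=float(d), arm=config.treated_label, censored=bool(f))
        for d, f in zip(treated, tflags)
    ] + [
        DurationRecord(duration=float(d), arm=config.control_label, censored=bool(f))
        for d, f in zip(control, cflags)
    ]
    return SimulatedTrial(
        ipd=IPDTrial(records=tuple(records), label="simulated"),
        resampled_treated=resampled,
        high_resample_warning=resampled > 0.1 * config.n_treated,
    )


# ---------------------------------------------------------------------------
# template-matched reconstructions


#: published censoring days: 1996 trial had 2 zinc patients censored on days
#: 9 and 11 and 6 placebo patients censored on days 7-19 (4 on day 15+)
_MOSSAD_CENSOR_DAYS = {"zinc": [9, 11], "placebo": [7, 7, 15, 15, 16, 19]}


def _integer_arm_matching(
    n: int, mean: float, sd: float, rng: np.random.Generator, tol: float = 0.02
) -> np.ndarray:
    """Draw an integer-day sample of size n with moments close to targets.

    Starts from a gamma draw rounded to days and then repairs the sample by
    +/- 1-day moves until the sample mean and SD are within ``tol``
    (relative) of the targets. Deterministic given the generator state.
    """
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    x = np.maximum(1.0, np.round(rng.gamma(shape, scale, size=n)))
    for _ in range(20000):
        m_err = (x.mean() - mean) / mean
        s_err = (x.std(ddof=1) - sd) / sd
        if abs(m_err) <= tol and abs(s_err) <= tol:
            break
        if abs(m_err) > tol:
            # move one value toward the target mean
            if m_err > 0:
                candidates = np.flatnonzero(x > 1)
                x[rng.choice(candidates)] -= 1
            else:
                x[rng.integers(0, n)] += 1
        else:
            # adjust spread symmetrically to keep the mean: push one value
            # away from (or toward) the mean and another the opposite way
            above = np.flatnonzero(x > x.mean())
            below = np.flatnonzero((x < x.mean()) & (x > 1))
            if above.size == 0 or below.size == 0:
                x[rng.integers(0, n)] += 1 if s_err < 0 else 0
                continue
            i, j = rng.choice(above), rng.choice(below)
            if s_err < 0:  # spread too small: move apart
                x[i] += 1
                x[j] -= 1
            else:  # spread too large: move together
                if x[i] > 1:
                    x[i] -= 1
                x[j] += 1
    return x


def trial_like(template: str, seed: int | None = None) -> IPDTrial:
    """Generate integer-day IPD matching a packaged trial's marginals.

    ``template`` is ``"mossad"`` (zinc gluconate 1996: n = 49/50, means
    5.20/9.20, SDs 2.83/5.32, with the published censoring pattern) or
    ``"petrus"`` (zinc acetate 1998: n = 52/49, means 5.29/7.06, SDs
    2.57/3.91, no censoring). Arm sizes are exact; means and SDs land within
    a few percent of the published values. Different seeds give different
    realizations with the same marginal targets.
    """
    templates = {"mossad": MOSSAD, "petrus": PETRUS}
    if template not in templates:
        raise ValueError(f"unknown template {template!r} (choose mossad or petrus)")
    summary = templates[template]
    rng = np.random.default_rng(seed)
    records: list[DurationRecord] = []
    for arm in (summary.treated, summary.control):
        x = _integer_arm_matching(arm.n, arm.mean, arm.sd, rng)
        flags = np.zeros(arm.n, dtype=bool)
        if template == "mossad":
            # mark the records closest to the published censoring days
            taken: set[int] = set()
            for day in _MOSSAD_CENSOR_DAYS[arm.label]:
                order = np.argsort(np.abs(x - day))
                idx = next(int(i) for i in order if int(i) not in taken)
                taken.add(idx)
                flags[idx] = True
        records.extend(
            DurationRecord(duration=float(d), arm=arm.label, censored=bool(f))
            for d, f in zip(x, flags)
        )
    return IPDTrial(records=tuple(records), label=f"{template}-like")
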