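"""Core data containers and CSV I/O for summary-level and patient-level trial data.

Two levels of data are supported, mirroring what is available in practice:

* **summary level** — per-arm sample size, mean and SD of the outcome (with
  optional quantiles), the form in which trial results are usually published;
* **individual patient data (IPD)** — one duration record per patient with an
  arm label and an optional right-censoring flag.

Durations are measured in days throughout. Censored records carry their
censoring day as the recorded duration: moment and quantile summaries treat
that day as the recovery day, while survival analyses respect the flag. This
dual convention lets the same record list feed both kinds of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmSummary",
    "TrialSummary",
    "DurationRecord",
    "IPDTrial",
    "read_ipd",
    "write_ipd",
    "read_summaries",
    "summarize_arm",
    "summarize_ipd",
]


@dataclass(frozen=True)
class ArmSummary:
    """Summary statistics for one trial arm.

    Parameters
    ----------
    label : str
        Arm name, e.g. ``"zinc"`` or ``"placebo"``.
    n : int
        Number of patients; must be at least 2.
    mean : float
        Arithmetic mean duration in days; must be positive.
    sd : float
        Sample standard deviation (n-1 divisor) in days; non-negative.
    quantiles : dict, optional
        Map from probability in (0, 1) to the duration quantile in days.
    """

    label: str
    n: int
    mean: float
    sd: float
    quantiles: Mapping[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"arm {self.label!r}: need n >= 2, got {self.n}")
        if not self.mean > 0:
            raise ValueError(f"arm {self.label!r}: mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"arm {self.label!r}: sd must be >= 0, got {self.sd}")
        if self.quantiles is not None:
            probs = sorted(self.quantiles)
            if any(not 0 < p < 1 for p in probs):
                raise ValueError("quantile probabilities must lie in (0, 1)")
            vals = [self.quantiles[p] for p in probs]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("quantiles must be non-decreasing in probability")
            object.__setattr__(self, "quantiles", dict(zip(probs, vals)))

    @property
    def variance(self) -> float:
        return self.sd**2

    @property
    def se_mean(self) -> float:
        """Standard error of the arm mean."""
        return self.sd / np.sqrt(self.n)


@dataclass(frozen=True)
class TrialSummary:
    """A two-arm trial at summary level: a treated and a control arm."""

    treated: ArmSummary
    control: ArmSummary
    label: str = ""

    def __post_init__(self) -> None:
        if self.treated.label == self.control.label:
            raise ValueError("treated and control arm labels must be distinct")
        if not self.control.mean > 0:
            raise ValueError("control mean must be > 0 for relative-scale analysis")


@dataclass(frozen=True)
class DurationRecord:
    """One patient's outcome: duration in days, arm label, censoring flag."""

    duration: float
    arm: str
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class IPDTrial:
    """Individual patient data for a two-arm trial."""

    records: tuple[DurationRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        arms = self.arm_labels
        if len(arms) != 2:
            raise ValueError(f"expected exactly 2 arms, found {len(arms)}: {arms}")
        for arm in arms:
            if sum(r.arm == arm for r in self.records) < 2:
                raise ValueError(f"arm {arm!r} has fewer than 2 records")

    @property
    def arm_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.records:
            if r.arm not in seen:
                seen.append(r.arm)
        return tuple(seen)

    def arm_durations(self, arm: str) -> np.ndarray:
        out = np.array([r.duration for r in self.records if r.arm == arm], dtype=float)
        if out.size == 0:
            raise KeyError(f"no records for arm {arm!r}")
        return out

    def arm_censor_flags(self, arm: str) -> np.ndarray:
        return np.array([r.censored for r in self.records if r.arm == arm], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "duration": [r.duration for r in self.records],
                "arm": [r.arm for r in self.records],
                "censored": [int(r.censored) for r in self.records],
            }
        )


#: default column names for IPD CSV files; override via ``columns=``
DEFAULT_IPD_COLUMNS = {"duration": "duration", "arm": "arm", "censored": "censored"}


def read_ipd(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    label: str = "",
) -> IPDTrial:
    """Read individual patient data from a CSV file.

    The file must have a header row. Expected columns (renameable through
    ``columns``): ``duration`` (positive number of days), ``arm`` (exactly two
    distinct levels) and optionally ``censored`` (0/1); a missing censoring
    column means no patient was censored.

    Raises
    ------
    ValueError
        If a duration fails to parse or is non-positive (the offending row is
        named), or if the arm column does not have exactly two levels.
    """
    cols = dict(DEFAULT_IPD_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("duration", "arm"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing required column {cols[key]!r} in {path}")

    durations = pd.to_numeric(df[cols["duration"]], errors="coerce")
    bad = durations.isna() | (durations <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"row {row + 1}: duration {df[cols['duration']].iloc[row]!r} "
            "is not a positive number"
        )

    arms = df[cols["arm"]].astype(str)
    levels = arms.unique()
    if len(levels) != 2:
        raise ValueError(f"arm column must have exactly 2 levels, found {len(levels)}")

    if cols["censored"] in df.columns:
        censored = df[cols["censored"]].astype(int).astype(bool)
    else:
        censored = pd.Series(False, index=df.index)

    records = [
        DurationRecord(duration=float(d), arm=a, censored=bool(c))
        for d, a, c in zip(durations, arms, censored)
    ]
    return IPDTrial(records=tuple(records), label=label or str(Path(path).stem))


def write_ipd(trial: IPDTrial, path: str | Path) -> None:
    """Write an :class:`IPDTrial` as a CSV that :func:`read_ipd` round-trips."""
    trial.to_frame().to_csv(path, index=False)


def read_summaries(path: str | Path) -> list[TrialSummary]:
    """Read summary-level trial data from a CSV file.

    Expected columns: ``trial, arm, role, n, mean, sd`` plus optional quantile
    columns ``q25, q50, q75, q90``. ``role`` is ``treated`` or ``control``.
    Returns one :class:`TrialSummary` per distinct trial label.
    """
    df = pd.read_csv(path)
    required = {"trial", "arm", "role", "n", "mean", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV missing columns: {sorted(missing)}")
    qcols = {0.25: "q25", 0.50: "q50", 0.75: "q75", 0.90: "q90"}
    trials = []
    for trial_label, grp in df.groupby("trial", sort=False):
        arms = {}
        for _, row in grp.iterrows():
            quants = {
                p: float(row[c])
                for p, c in qcols.items()
                if c in grp.columns and pd.notna(row[c])
            }
            arms[row["role"]] = ArmSummary(
                label=str(row["arm"]),
                n=int(row["n"]),
                mean=float(row["mean"]),
                sd=float(row["sd"]),
                quantiles=quants or None,
            )
        if set(arms) != {"treated", "control"}:
            raise ValueError(
                f"trial {trial_label!r}: need one 'treated' and one 'control' row"
            )
        trials.append(
            TrialSummary(treated=arms["treated"], control=arms["control"],
                         label=str(trial_label))
        )
    return trials


def summarize_arm(
    durations: Sequence[float],
    censoring: Sequence[bool] | None = None,
    quantile_probs: Sequence[float] = (0.25, 0.5, 0.75),
    label: str = "",
    quantile_method: str = "linear",
) -> ArmSummary:
    """Summarize one arm's durations into an :class:`ArmSummary`.

    Censored durations enter the moments and quantiles at their censoring day
    (``censoring`` is accepted for interface symmetry and recorded nowhere in
    the summary). The quantile rule defaults to linear interpolation, the
    common default of mainstream statistics environments; any method accepted
    by :func:`numpy.quantile` may be passed.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 durations, got {x.size}")
    quants = None
    if quantile_probs:
        qv = np.quantile(x, list(quantile_probs), method=quantile_method)
        quants = dict(zip((float(p) for p in quantile_probs), (float(v) for v in qv)))
    return ArmSummary(
        label=label,
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        quantiles=quants,
    )


def summarize_ipd(
    trial: IPDTrial,
    treated_arm: str | None = None,
    quantile_probs: Sequence[float] = (0.25, 0.5, 0.75, 0.9),
    quantile_method: str = "linear",
) -> TrialSummary:
    """Collapse an IPD trial to a :class:`TrialSummary`.

    ``treated_arm`` names the treated arm; by default the first arm
    encountered in the record list is taken as treated.
    """
    arms = trial.arm_labels
    treated = treated_arm if treated_arm is not None else arms[0]
    if treated not in arms:
        raise KeyError(f"arm {treated!r} not present (arms: {arms})")
    control = arms[1] if treated == arms[0] else arms[0]
    mk = lambda a: summarize_arm(  # noqa: E731
        trial.arm_durations(a),
        quantile_probs=quantile_probs,
        label=a,
        quantile_method=quantile_method,
    )
    return TrialSummary(treated=mk(treated), control=mk(control), label=trial.label)
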