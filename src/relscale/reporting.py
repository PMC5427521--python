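"""Report assembly and deterministic rendering (text, JSON, CSV).

An :class:`AnalysisReport` collects everything one analysis produced — the
summary table on both scales, effect estimates under the requested CI
methods, scale diagnostics and survival results — together with a
provenance block (seed, reps, package version, configuration) so that a
rendered report can be reproduced exactly. Rendering is pure: the same
report and config always produce byte-identical output.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field as dc_field
from typing import Any

import pandas as pd

from . import __version__
from .relative_scale import EffectEstimate, RelativeTrialSummary
from .data_model import TrialSummary

__all__ = ["AnalysisReport", "render_report", "forest_frame"]

#: display rounding, mirroring how trial tables are conventionally printed
ROUND_PCT = 1  # decimals on percentages
ROUND_DAYS = 2  # decimals on days


@dataclass
class AnalysisReport:
    """Everything one trial analysis produced, ready for rendering."""

    label: str
    summary: TrialSummary | None = None
    relative_summary: RelativeTrialSummary | None = None
    effects: list[EffectEstimate] = dc_field(default_factory=list)
    diagnostics: dict[str, Any] = dc_field(default_factory=dict)
    survival: dict[str, Any] = dc_field(default_factory=dict)
    provenance: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("package", f"relscale {__version__}")


def _effects_frame(effects: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scale": [e.scale for e in effects],
            "method": [e.method for e in effects],
            "point": [e.point for e in effects],
            "ci_low": [e.ci_low for e in effects],
            "ci_high": [e.ci_high for e in effects],
            "level": [e.level for e in effects],
        }
    )


def _round_for_scale(value: float, scale: str) -> float:
    nd = ROUND_PCT if "percent" in scale or scale == "smd" else ROUND_DAYS
    return round(value, nd)


def _render_text(report: AnalysisReport) -> str:
    out = io.StringIO()
    w = out.write
    w(f"Trial: {report.label}\n")
    if report.summary is not None:
        s = report.summary
        w("\nSummary (days)\n")
        w(f"  {'arm':<12}{'n':>5}{'mean':>8}{'sd':>8}\n")
        for arm in (s.treated, s.control):
            w(f"  {arm.label:<12}{arm.n:>5}{arm.mean:>8.2f}{arm.sd:>8.2f}\n")
    if report.relative_summary is not None:
        r = report.relative_summary
        w("\nTransformation to the %-scale (control mean = 100)\n")
        w(f"  {'arm':<12}{'mean %':>8}{'sd %':>8}\n")
        w(f"  {'treated':<12}{r.treated_mean_pct:>8.{ROUND_PCT}f}"
          f"{r.treated_sd_pct:>8.{ROUND_PCT}f}\n")
        w(f"  {'control':<12}{r.control_mean_pct:>8.{ROUND_PCT}f}"
          f"{r.control_sd_pct:>8.{ROUND_PCT}f}\n")
    if report.effects:
        w("\nEffect estimates\n")
        for e in report.effects:
            lo = _round_for_scale(e.ci_low, e.scale)
            hi = _round_for_scale(e.ci_high, e.scale)
            pt = _round_for_scale(e.point, e.scale)
            unit = "%" if "percent" in e.scale else ""
            w(f"  {e.scale:<18}{e.method:<24}{pt}{unit} "
              f"({int(e.level * 100)}% CI {lo} to {hi})\n")
    if report.diagnostics:
        w("\nScale diagnostics\n")
        for key, val in report.diagnostics.items():
            w(f"  {key}: {val}\n")
    if report.survival:
        w("\nSurvival analysis\n")
        for key, val in report.survival.items():
            w(f"  {key}: {val}\n")
    w("\nProvenance\n")
    for key in sorted(report.provenance):
        w(f"  {key}: {report.provenance[key]}\n")
    return out.getvalue()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def _render_json(report: AnalysisReport) -> str:
    payload = {
        "label": report.label,
        "summary": _jsonable(report.summary) if report.summary else None,
        "relative_summary": (
            _jsonable(report.relative_summary) if report.relative_summary else None
        ),
        "effects": _jsonable(report.effects),
        "diagnostics": _jsonable(report.diagnostics) or None,
        "survival": _jsonable(report.survival) or None,
        "provenance": _jsonable(report.provenance),
    }
    payload = {k: v for k, v in payload.items() if v is not None}
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def render_report(report: AnalysisReport, format: str = "text") -> str:
    """Serialize a report deterministically.

    ``format`` is ``text`` (fixed-width human-readable block), ``json``
    (sorted keys, re-parseable) or ``csv`` (the tidy effects table).
    Empty sections are omitted, never rendered blank.
    """
    if format == "text":
        return _render_text(report)
    if format == "json":
        return _render_json(report)
    if format == "csv":
        return _effects_frame(report.effects).to_csv(index=False)
    raise ValueError(f"unknown report format {format!r}")


def forest_frame(pooled, per_study: bool = True) -> pd.DataFrame:
    """Forest-plot-ready table from a :class:`~relscale.meta_pool.PooledResult`.

    One row per study (label, point, ci_low, ci_high, weight %) and a final
    ``pooled`` row.
    """
    from scipy import stats

    rows = []
    if per_study:
        z = stats.norm.ppf(0.5 + pooled.level / 2)
        for _, r in pooled.weights.iterrows():
            rows.append(
                {
                    "label": r["label"],
                    "point": r["point"],
                    "ci_low": r["point"] - z * r["se"],
                    "ci_high": r["point"] + z * r["se"],
                    "weight_pct": r["weight_pct"],
                }
            )
    rows.append(
        {
            "label": "pooled",
            "point": pooled.point,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
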