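"""Published summary statistics of the two zinc-lozenge trials.

Two randomized placebo-controlled trials of zinc lozenges for the common cold
serve as the package's worked example: Mossad et al. (1996, zinc gluconate,
n = 49/50) and Petrus et al. (1998, zinc acetate, n = 52/49). Their published
per-arm sample sizes, mean durations, SDs and duration quantiles are packaged
here as :class:`~relscale.data_model.TrialSummary` constants so every
summary-level operation can be exercised against real published numbers
without any external files.
"""

from __future__ import annotations

from .data_model import ArmSummary, TrialSummary

__all__ = ["MOSSAD", "PETRUS", "published_trials"]

MOSSAD = TrialSummary(
    label="mossad_1996",
    treated=ArmSummary(
        label="zinc",
        n=49,
        mean=5.20,
        sd=2.83,
        quantiles={0.25: 3.0, 0.50: 5.0, 0.75: 7.0, 0.90: 9.0},
    ),
    control=ArmSummary(
        label="placebo",
        n=50,
        mean=9.20,
        sd=5.32,
        quantiles={0.25: 5.0, 0.50: 8.0, 0.75: 14.0, 0.90: 17.0},
    ),
)

PETRUS = TrialSummary(
    label="petrus_1998",
    treated=ArmSummary(
        label="zinc",
        n=52,
        mean=5.29,
        sd=2.57,
        quantiles={0.25: 3.0, 0.50: 5.0, 0.75: 7.0, 0.90: 8.0},
    ),
    control=ArmSummary(
        label="placebo",
        n=49,
        mean=7.06,
        sd=3.91,
        quantiles={0.25: 4.0, 0.50: 6.0, 0.75: 8.0, 0.90: 14.0},
    ),
)


def published_trials() -> list[TrialSummary]:
    """The two packaged trials, in publication order."""
    return [MOSSAD, PETRUS]
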