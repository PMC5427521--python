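# relscale

Relative-scale (ratio-of-means) analysis of continuous trial outcomes.

Duration-type outcomes — how long an illness lasts, how long a patient stays
in hospital — are conventionally analyzed and meta-analyzed as mean
differences in their original units (days). But a treatment that shortens
*every* episode by the same number of days predicts impossible (zero or
negative) durations for short episodes and leaves the control arm's spread
untouched, while a treatment that shortens every episode by the same
*percentage* respects the positive support of the data and shrinks the
spread proportionally. `relscale` is a library (plus a thin CLI) for
biostatisticians and meta-analysts who want to analyze such outcomes on the
relative scale and to test, against data, which scale an observed effect
actually lives on.

## What it computes

Given a treated and a control arm with means m̄_t, m̄_c, standard deviations
s_t, s_c and sizes n_t, n_c:

- **%-of-control transformation** — divide each arm's mean and SD by m̄_c
  and multiply by 100, so the control mean becomes 100% and the treated mean
  becomes the ratio of means RoM = m̄_t / m̄_c in percent. The relative
  effect is 100·(RoM − 1). The transformation is linear, so the two-sample
  t test is identical to the one on the original days scale.
- **Five confidence intervals for the relative effect**: the normalized-t
  interval (the pooled-variance t interval for m̄_t − m̄_c rescaled by
  m̄_c); a pooled-t interval on log durations, back-transformed (IPD only);
  the delta-method (Taylor-series) interval with
  SE(ln RoM) = √(s_t²/(n_t m̄_t²) + s_c²/(n_c m̄_c²));
  Fieller's interval for the ratio of two normal means (unequal-variance
  form, flags its unbounded cases); and a stratified BCa bootstrap under a
  fixed-denominator or ratio resampling scheme (IPD only).
- **Scale diagnostics** — apply a candidate effect (a shift of *m* days or a
  scaling of *p* %) to every control duration and compare the prediction
  with the actual treated arm: the count of impossible (≤ 0 day)
  predictions, a variance-ratio F test of predicted vs observed spread, and
  per-quantile contrasts with bootstrap CIs.
- **Recovery-time survival analysis** — Kaplan–Meier curves, the logrank
  test, and a single-binary-covariate Cox fit (Efron or Breslow ties) whose
  exponentiated coefficient is the rate ratio of recovery.
- **Meta-analytic pooling** — inverse-variance fixed- and random-effects
  (DerSimonian–Laird) pooling with Q, I², τ² and Z, run side by side on the
  days, %-of-control and SMD scales to compare heterogeneity across scales.
- **Synthetic trials** — a generator of integer-day duration trials with
  multiplicative or additive effects, optional censoring, and templates
  matched to the two packaged zinc-lozenge trials, so every IPD-level
  operation is testable without external data.

Two published placebo-controlled zinc-lozenge trials for the common cold
(Mossad 1996, n = 49/50; Petrus 1998, n = 52/49) ship as summary-level
constants (`relscale.MOSSAD`, `relscale.PETRUS`) and drive the worked
examples.

## Worked example

```python
import relscale as rs

rel = rs.to_relative(rs.PETRUS)
print(rel.treated_mean_pct)   # 74.92917847025497  (zinc mean as % of placebo)

md = rs.effect_absolute(rs.PETRUS)
print(md.point, md.ci_low, md.ci_high)
# -1.77 -3.069158427283382 -0.4708415727166171   (days)

e = rs.effect_relative(rs.PETRUS, method="normalized-t")
print(e.point, e.ci_low, e.ci_high)
# -25.070821529745036 -43.47249897001958 -6.669144089470498   (percent)
```

Zinc shortened colds by 1.77 days on the absolute scale; on the relative
scale the same trial says colds were 25.1% shorter (95% CI −43.5 to −6.7%),
a statement that applies to 2-day and 2-week colds alike. The example
scripts under `examples/` walk through each capability:

```sh
python examples/summary_effects.py        # Table-style effects on all scales
python examples/scale_diagnosis.py        # shift vs scaling diagnosis
python examples/ipd_workflow.py           # five CIs + survival on IPD
python examples/pooling_heterogeneity.py  # heterogeneity across scales
python examples/simulate_trials.py        # generator + coverage mini-study
```

`examples/scale_diagnosis.py` prints, for integer-day data matched to the
Mossad trial's marginals, that a uniform 4.0-day shortening predicts 7
impossible cold durations and fails the variance test (P ≈ 1e-5), while a
uniform 43% shortening predicts none and is consistent with the zinc arm's
spread (P ≈ 0.5) — the scale diagnosis in one screen.

A CLI mirrors the library:

```sh
relscale analyze-summary --input summaries.csv --scale relative --method taylor
relscale simulate --template petrus --seed 1 --out ipd.csv
relscale diagnose --input ipd.csv --scale absolute --magnitude 1.77
relscale pool --input summaries.csv --scale relative --model random
```

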