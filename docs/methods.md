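# Methods

## The problem and the model

Let a two-arm randomized trial measure a positive continuous outcome — here
the duration of a common cold in days — with treated-arm mean m̄_t, SD s_t,
size n_t, and control-arm m̄_c, s_c, n_c. Two candidate effect models make
sharply different predictions:

- **additive (absolute scale)**: every episode is shortened by a constant
  m days. Applied to the control distribution this is a left-translation:
  the predicted treated distribution keeps the control variance exactly and
  assigns durations ≤ 0 to any control episode shorter than m days —
  durations that cannot occur.
- **multiplicative (relative scale)**: every episode is shortened by a
  constant fraction p %, i.e. multiplied by f = 1 − p/100 ∈ (0, 1]. The
  predicted mean and SD are both scaled by f (variance by f²), and positive
  data stay positive.

The package's diagnostic (`scale_diagnostics.diagnose`) applies each
candidate to the control arm's individual durations and reports (i) the
impossible-prediction count, (ii) a variance-ratio F test of the predicted
against the actual treated arm, and (iii) quantile contrasts. It
deliberately emits evidence rather than a verdict: the choice of scale is a
judgment about the biology of the outcome (a duration has a meaningful 0%
target and a meaningful 100% baseline; a blood pressure does not), and the
diagnostic quantifies which model the data tolerate.

The two exact transformation laws (shift preserves variance; scaling by f
scales the SD by f) double as machine-precision test oracles, which is why
predicted durations are kept continuous: re-rounding them to whole days
would corrupt the laws while adding nothing to the inference. Day-rounding
is a display concern.

## The %-of-control transformation

`to_relative` divides both arms' means and SDs by m̄_c and multiplies by
100. The control mean becomes exactly 100, the treated mean becomes the
ratio of means in percent, and each arm's coefficient of variation is
preserved exactly. Because the map is linear, the two-sample t statistic on
transformed values equals the days-scale statistic to machine precision;
the transformation changes the reporting unit, not the evidence. The
relative effect is 100·(RoM − 1), negative for a beneficial shortening.

## Interval constructions and their relationships

Five constructions are implemented (`inference`); all are two-sided and
default to level 0.95.

1. **normalized-t**: the pooled-variance two-sample t interval for
   m̄_t − m̄_c, divided by m̄_c and multiplied by 100. Transparent (SDs and
   n's stay visible in forest plots) but treats the denominator as fixed.
   Under a genuinely multiplicative effect the denominator's sampling
   variation partially cancels in the ratio, so this interval is
   systematically the widest — see "Known limitations" for the coverage
   consequence. The pooled-variance (rather than Welch) form is the
   default because it is the form whose bounds the packaged trials'
   published intervals reproduce to printed precision; Welch is an option.
2. **log-t** (IPD only): pooled t interval for the difference of mean log
   durations, back-transformed via 100·(exp(·) − 1). Log transformation
   approximately equalizes arm variances under a multiplicative effect.
3. **taylor**: delta-method interval on ln RoM with
   SE² = s_t²/(n_t m̄_t²) + s_c²/(n_c m̄_c²), normal quantiles on the log
   scale (a t-quantile variant is exposed), exponentiated.
4. **fieller**: the confidence set {ρ : (m̄_t − ρ m̄_c)² ≤ t² (v_t + ρ² v_c)}
   with v = s²/n, solved as a quadratic. Unequal-variance form by default
   with Satterthwaite degrees of freedom evaluated at the point-estimate
   ratio. When the quadratic's leading coefficient is not positive the set
   is a complement-of-interval or the whole line; the result is flagged
   `unbounded`, never silently truncated.
5. **bootstrap** (IPD only): nonparametric resampling stratified by arm,
   BCa endpoints with the bias-correction from the replicate distribution
   and acceleration from the leave-one-out jackknife over both arms.
   Default 9999 replicates. Two schemes: `ratio` resamples
   100·(m̄_t*/m̄_c* − 1); `normalized-difference` first fixes the observed
   control mean as the 100% denominator and resamples the difference of
   per-arm means on that scale.

On the packaged summary data the normalized-t interval strictly contains
both the Taylor and Fieller intervals for both trials; Taylor and Fieller
agree to ~3 significant figures whenever the denominator is precise (the
delta-method limit of Fieller).

## Hypothesis tests

- `variance_ratio_test`: F = (s_a/s_b)² on (n_a−1, n_b−1) df, two-sided
  p = 2·min(tails), the var.test convention.
- `two_sample_t`: pooled or Welch–Satterthwaite; both-constant samples with
  equal means return p = 1 by convention.
- `permutation_test`: Fisher–Pitman with the difference in arm means as the
  statistic; exact enumeration when C(n, n₁) ≤ `max_exact_n` (default 10⁵),
  otherwise Monte-Carlo with the observed assignment counted in the
  numerator (so p ≥ 1/(reps+1)).
- survival: logrank (rho = 0) and Kaplan–Meier delegate to lifelines; the
  Cox fit for the single binary covariate maximizes the partial likelihood
  by Newton iteration with step-halving (convergence when the relative
  log-likelihood change < 1e-9, max 50 iterations), Efron ties by default
  and Breslow as an alternative. A monotone likelihood (complete risk-set
  separation) is reported as non-converged with an unbounded upper CI
  rather than a spurious finite estimate. The score test at β = 0 with
  Breslow ties equals the logrank statistic on tie-free data, which the
  suite checks.

## Censoring convention

A censored record carries its censoring day as its duration. Moment and
quantile summaries, and the scale diagnostics, treat that day as the
recovery day; survival operations treat the record as censored. This dual
convention matches how duration tables are published (censored patients are
included in means) while keeping the survival analysis honest. It biases
moment summaries downward when censoring is early; in the packaged trials
most censoring occurred late in follow-up, where the bias is small.

## Meta-analytic pooling

`pool` implements inverse-variance pooling: fixed-effect weights 1/se²;
random-effects by DerSimonian–Laird, τ² = max(0, (Q − df)/(Σw − Σw²/Σw)),
chosen over REML as the estimator of the era's standard meta-analysis
tooling. Q and I² = max(0, (Q − df)/Q)·100 are computed from fixed-effect
weights; the heterogeneity p-value is the χ²_df tail of Q.
`scale_comparison` builds per-trial effects on three scales — the mean
difference with its pooled-t SE, the relative effect with that SE rescaled
by m̄_c·100 (the %-of-control transformation applied to the SE), and
Hedges' g with its large-sample SE — and pools each. Families of trials
that are exact rescalings of one trial have Q = 0 on the relative scale and
Q > 0 on the days scale, and vice versa for pure shift families; the suite
asserts both constructions.

## Standardized mean difference

Hedges' g by default (exact small-sample correction factor
J = Γ(df/2)/(√(df/2)·Γ((df−1)/2))), Cohen's d as an option, normal-theory
CI from the usual large-sample variance. The SMD is included because it is
the other scale meta-analysts reach for, not because it is recommended: a
"0.97 SD units" effect answers no patient's question, and the package's
purpose is precisely the alternative.

## The synthetic generator

`simulate_trial` draws the control arm from a lognormal, gamma or
discrete-uniform-days baseline parameterized by target mean and SD
(defaults 7.0 and 3.5 days — a coefficient of variation of 0.5, between the
two packaged trials' placebo arms), applies a multiplicative (ratio,
default 0.75) or additive (days) effect to independent treated-arm draws,
optionally censors a fraction of each arm (administrative cut-day or random
early stopping), and optionally rounds to whole days (half-up, floor 1 day,
mimicking daily symptom diaries; unrounded mode exists so the exact
variance laws remain testable). Additive-effect draws landing at ≤ 0 days
are redrawn, with the count reported and a warning flag when more than 10%
of the arm needed redrawing — real durations cannot be non-positive, and
the collision rate is itself a measure of how badly an additive model fits
a duration outcome.

`trial_like` produces integer-day reconstructions matched to the packaged
trials' published marginals: exact arm sizes, means and SDs within 2% by
construction (a gamma draw rounded to days, then repaired by ±1-day moves
that alternate between recentering and re-spreading), and the published
censoring pattern for the 1996 trial (zinc: days 9 and 11; placebo: six
patients, four on day 15 or later). What the generator does *not* emulate:
the per-day histogram shapes of the source trials, serial features such as
weekday effects, and any correlation between arms. Passing tests on
synthetic data therefore demonstrate correctness of the machinery and
qualitative reproduction of the published contrasts, not numerical identity
with the unpublished patient data — the published impossible-counts (12 and
3), within-trial variance-test p-values, logrank p-values and Cox rate
ratios depend on the original IPD and are reproduced here only in kind
(e.g. a typical reconstruction gives Cox RR ≈ 2.5 where 2.7 was published).

## Numerical choices

- Quantiles use linear interpolation (the numpy/R type-7 default)
  everywhere, exposed as a parameter; the packaged trials' published
  quantiles are integers under any common rule.
- Variance tests on diagnostic predictions are computed from moments
  directly, since a shifted prediction can have non-positive values for
  which no valid arm summary exists.
- BCa degenerate cases (all replicates identical) collapse to a zero-width
  interval at the point estimate; the bias-correction proportion is clipped
  to (1/(B+1), B/(B+1)) to keep z₀ finite.
- CSV round-trips use full round-trip float parsing so written IPD reloads
  bit-identically.
- Bootstrap and permutation reproducibility: all randomness flows through
  `numpy.random.default_rng(seed)`; the same seed gives identical results.

## Simulation study sizes

The coverage study used by the test-suite and the acceptance script runs
500 simulated trials (ratio 0.75, n = 50/arm, lognormal baseline) with 999
bootstrap replicates per trial; quantile bootstraps use 1999 replicates.
These sizes put the Monte-Carlo SE of a 95% coverage estimate near 1
percentage point, small against the effects being measured, while keeping
the full study under a few seconds.

## Known limitations

- **Normalized-t coverage under a multiplicative effect.** Because the
  normalized-t interval treats the control mean as a fixed rescaling
  constant, its half-width relative to the sampling SD of the ratio
  estimator is ≈ z·√(1+R²)/(R√2) for true ratio R — about 2.33σ at
  R = 0.75, for any finite-variance baseline. Its empirical coverage of the
  true relative effect is therefore ≈ 98%, not 95%, under a genuinely
  multiplicative effect: it is conservative by construction, which is the
  same property that makes it the widest interval in the method ordering.
  The fixed-denominator bootstrap scheme inherits a milder version of the
  same conservatism. Users wanting nominal-coverage intervals for the
  ratio should prefer the Taylor, Fieller or ratio-scheme bootstrap
  intervals.
- **Variance-test calibration is kurtosis-sensitive.** The F test's size is
  exact only under normality. Under the generator's skewed baselines its
  type-I rate at α = 0.05 ranges from ~0 (uniform-days) to ~0.25
  (lognormal) at n = 40/arm. The diagnostic's variance test should be read
  as descriptive evidence alongside the impossible-count, not as a
  calibrated test on heavy-tailed data; the suite checks exact calibration
  on normal samples and conservative behavior on uniform-day data.
- The Cox fitter handles exactly one binary covariate; no multi-covariate
  models, time-varying effects or proportionality diagnostics.
- Fieller's unbounded cases are flagged, and downstream width comparisons
  are undefined for them by design.
- The SMD's CI uses the large-sample normal approximation; exact
  noncentral-t intervals are out of scope.
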