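# Methods

## Cohorts and the follow-up clock

A cohort is every person of one sex born in one calendar year who survived
until January 1 of the year of their 60th birthday (`t0`). That date is day
`t = 0` of the follow-up clock, so the seasonal phase is aligned across
members regardless of birth day. A member born on day-of-year `b`
(January 1 → 0) is `365 - b + t` days past their 59th birthday on day `t`;
this offset is how age enters the hazard.

Follow-up ends on December 31 of the year members would turn 95. The grid
indexes actual calendar days, so leap years make some grids a day longer,
while the model's seasonal period is fixed at 365.25 days. Deaths after the
grid end are right-censored: the person contributes exposure on every grid
day but no event. Daily mortality rates at ages above 95 are too noisy to
constrain the fit, and under realistic parameters well under 2% of deaths
are censored by this cut (the acceptance run reports ~0.6%).

Day-count conventions: a person dying on day `t` is counted in the risk set
`N_t` (alive at the beginning of the day) and in the death count `d_t`.
Records with unparseable dates are dropped with a logged count; no
imputation is attempted. Sex codes are mapped through a configurable table
(`M/F`, `man/kvinna`, `1/2`, ...), and an unknown code is an error rather
than a silent drop.

The follow-up start age is fixed at 60 throughout the package; it is a
structural constant of the cohort definition, not a configuration knob.

## Estimation

The hazard is `λ(t|b) = μ e^{β(t+365−b)} e^{α cos(ωt+θ)}`, `ω = 2π/365.25`.
Within a day the hazard is constant, so with `λ << 1` the daily death count
is approximately Poisson with mean `N_t λ(t)`, giving the log-linear model

```
log E(d_t) = log N_t + c + β t + a1 sin(ωt) + a2 cos(ωt)
```

fit by `statsmodels` Poisson GLM (IRLS). Days with `N_t = 0` are excluded
(the offset is undefined). The per-individual age offset `365 − b_i` cannot
appear in this aggregated regression; it is absorbed into the intercept, so
the reported `μ = exp(c)` is on the *cohort scale*, equal to the
individual-scale μ times `e^{β(365 − b̄)}` with `b̄` the cohort mean birth
day. Everything downstream (rate ratio, decomposition, life expectancy at
the mean-`b` policy) is invariant to this choice; the `individual` birth-day
policy and the direct likelihood undo it explicitly. The covariance matrix
is the GLM's inverse observed information over `(c, β, a1, a2)`, and a
2-df likelihood-ratio test of `a1 = a2 = 0` accompanies every fit.

`fit_direct_ml` maximizes the exact discrete-day survival likelihood — each
person contributes `exp(−λ_b(t))` per day alive and `1 − exp(−λ_b(t))` on
the death day, with their own `b` — via L-BFGS-B with an analytic gradient,
grouping people by birth day so the cost is a few cumulative sums per
evaluation. β is optimized in per-year units to condition the problem;
the covariance comes from a finite-difference Hessian of the gradient and is
reported on the same `(log μ_cohort, β, a1, a2)` scale as the Poisson fit.
On simulated 100,000-person cohorts the two routes agree to ≲0.05% relative
on `(β, a1, a2)`; the Poisson route is the default because it is faster and
uses standard software.

Amplitude and phase: `α = √(a1²+a2²)`, `θ = atan2(−a1, a2)` kept in
`(−π, π]` (the `−π` boundary maps to `+π`; `a1 = a2 = 0` returns `θ = 0`
with the amplitude itself flagging degeneracy).

## Rate ratio and its confidence interval

The within-year peak-to-trough hazard ratio is `h = exp(2α − 182.625 β)`:
`2α` spans the sinusoid's range and `182.625 β` removes the Gompertz drift
accrued over the half year separating peak from trough. CIs are parametric
bootstrap: draw `(β, a1, a2)` from the fit's multivariate normal (intercept
marginalized out — it cancels from `h`), push each draw through the polar
transform and the formula, and take empirical percentiles. Defaults:
10,000 draws, 95% level, one explicit integer seed per call. The percentile
interval (rather than a log-normal approximation) follows the empirical-
distribution definition of the interval; 1,000-replicate simulations show
93–97% coverage at the nominal 95% level. The covariance is validated as
symmetric PSD before sampling (eigenvalue check with a relative `1e-12`
floor).

The winter peak falls on day `(−θ/ω) mod 365.25` from January 1.

## Decomposition and counterfactual life expectancy

`λ = M1 · M2` with `M1 = μ* e^{β(t+365−b)}`, `μ* = μ e^{−α}`, and
`M2 = e^{α(1+cos(ωt+θ))} ≥ 1`, equality at the seasonal trough. `M1` is the
lower-bound mortality — the rate that would prevail if late-summer
conditions held all year — and `M2` is a pure, age-independent seasonal
multiplier. The reconstruction `M1·M2 = λ` is an algebraic identity and is
tested to `1e-12` relative on dense grids.

Life expectancy integrates the lifetime density `f(t) = λ(t) e^{−∫λ}`
numerically with a piecewise-constant hazard: steps of `dt` days (default
1, matching the estimation discretization), hazard evaluated at step
midpoints, and the mean computed as `E[T] = ∫ S(t) dt` with the per-step
closed form `S_k (1 − e^{−λ_k dt})/λ_k`. This is exact for a constant
hazard (mean exactly `1/λ`), second-order accurate otherwise (halving `dt`
moves e₆₀ by ≪ 0.01 days), and matches adaptive quadrature of the
closed-form Gompertz density to < 0.05 days. Integration extends until
survival drops below `1e-10` or age 120, whichever comes first; reaching
the cap with more mass than that triggers a warning.

Expected follow-up days convert to mean age at death as
`59 + (365 − b + e)/365.25` years. The default `b` policy uses the cohort
mean birth day; an `individual` policy averages expected lifetimes over the
empirical birth-day distribution (on simulated data the two differ by
hundredths of a year, because the expectation is nearly linear in `b` over
its observed spread). The seasonality contribution of a cohort is
`e(M1) − e(M1·M2) ≥ 0` years. Since the cohorts are extinct, the observed
life expectancy is simply the members' mean age at death (exact day counts
/ 365.25), and on data simulated from the model the fitted `e_model`
reproduces it to ~0.01 years.

## The synthetic-data generator

`generate_study` emulates the person-level schema of a genealogical death
register: rows of (birth date, death date, sex). Birth days are uniform over
days 0–364 of the birth year (real registers show mild birth seasonality,
which is deliberately not modelled). Each person's death day is sampled from
their 59th birthday onward under the cohort's hazard, treating the hazard as
constant within each calendar day — sequential daily Bernoulli trials with
`p_t = 1 − e^{−λ(t|b)}`, implemented equivalently (and exactly, in law) by
inverse-CDF sampling of an Exp(1) clock against the cumulative hazard,
which factorizes so one cumulative sum serves a whole cohort. Draws are
capped at age 120 and flagged; under the default parameters the cap is
essentially never reached. People dying before `t0` are emitted — applying
the inclusion rule is the pipeline's job, and those records exercise it.

Each (sex, birth-year) cohort consumes an independent `SeedSequence`
substream spawned from the master seed, and per-person uniforms are drawn
as one vector per cohort, so output is deterministic and independent of
generation order.

Scenario parameters are linear trajectories across birth years in
field-natural quantities: the trough-level scale `μ*` (per day), the
Gompertz slope in per-year units, the rate ratio `h`, and the peak day.
The bundled default scenario is calibrated to plausible magnitudes for
19th-century European elderly mortality — 101 annual cohorts per sex
(1800–1900) of 23,000 people (≈4.7 M in total), slope 0.088/year,
`h` falling from 1.9 (men) / 2.1 (women) to 1.1, the peak drifting from
mid-February toward early March, and `μ*` declining so lower-bound life
expectancy improves by roughly two years over the century. These defaults
are implementation choices of the generator, not estimates from any real
register; passing tests on such data demonstrates internal consistency of
estimator and generator, not correctness on real registers, which contain
date errors, migration, register-coverage changes, influenza shocks and
phase drift that the generator deliberately omits.

## Numerical and design notes

* Convergence: the GLM stops at relative deviance change `1e-8` (statsmodels
  default, well beyond reporting precision); the direct likelihood uses
  L-BFGS-B with `ftol = 1e-14` on the scaled problem.
* Non-identifiable cohorts (no deaths on the grid) raise; the pipeline
  catches per-cohort failures, logs them into the manifest, and continues.
* `rate_ratio_ci` clamps the interval to contain the point estimate; with a
  symmetric sampling distribution this never binds in practice.
* The 60-day running-line smoother (centered moving average, truncated at
  the edges) is applied only in plots, never in estimation.
* Problem sizes in the test suite — one 100,000-person cohort for recovery
  and estimator equivalence, 1,000 replicates of 10,000-person cohorts for
  CI coverage, a 202-cohort × 23,000-person study in the acceptance script —
  were chosen so each check has the statistical resolution its tolerance
  requires.

## Known limitations

* Constant amplitude and phase within a cohort: calendar-year shocks
  (influenza years) and any amplitude–age interaction are outside the model.
* The Poisson approximation assumes `λ << 1` per day; fine for ages 60–95.
* No migration or competing exits: the risk set shrinks only by death.
* Life-expectancy conversion reports the conditional mean age at death given
  survival to `t0`; it is not a period life-table quantity.
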