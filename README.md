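# seasonmort

Seasonal fluctuations in cohort mortality among the elderly, and what their
decline contributed to the rise in life expectancy.

In temperate climates, death rates among people over 60 peak every winter and
bottom out in late summer. Over the 19th and 20th centuries the size of this
winter excess shrank dramatically. `seasonmort` follows **extinct
sex-specific birth cohorts** — everyone of one sex born in one calendar year
who survived until the year of their 60th birthday — and asks how much of the
concurrent gain in life expectancy at 60 is attributable to the quenching of
seasonality.

The package is aimed at demographers and epidemiologists working with
person-level vital records (birth date, death date, sex). It ships a
synthetic cohort generator that emulates that schema, so the entire analysis
runs and is tested offline.

## The model

With follow-up time *t* in days from January 1 of the year cohort members
turn 60, and *b* the birth day-of-year, the daily mortality rate of a cohort
is modelled as a Gompertz hazard modulated by a one-year sinusoid:

$$\lambda(t \mid b) = \mu\, e^{\beta (t + 365 - b)}\, e^{\alpha \cos(2\pi t/365.25 + \theta)}$$

* **μ** — baseline hazard scale (per day), **β** — exponential age slope (per day),
* **α ≥ 0** — seasonal amplitude on the log-hazard scale, **θ** — phase fixing
  the calendar timing of the winter peak.

Fitting uses the piecewise-exponential approximation: among the *N<sub>t</sub>*
people alive at the start of day *t*, the death count *d<sub>t</sub>* is
approximately Poisson with

$$\log E(d_t) = \log N_t + c + \beta t + a_1 \sin(2\pi t/365.25) + a_2 \cos(2\pi t/365.25),$$

a Poisson regression solved by `statsmodels`; amplitude and phase follow from
α = √(a₁² + a₂²), θ = arctan(−a₁/a₂). An exact per-individual survival
likelihood (`fit_direct_ml`) is included and agrees with the Poisson route to
well under 1%.

Three derived quantities summarize each cohort:

* **Rate ratio** *h* = exp(2α − 182.625 β): within-year peak-to-trough hazard
  ratio ("how many times deadlier is winter than summer"), with parametric
  bootstrap CIs from the fit's multivariate normal.
* **Decomposition** λ = M₁ · M₂ with M₁ = μ\*e^{β(t+365−b)} (μ\* = μe^{−α}),
  the age-only *lower-bound mortality* prevailing under permanent late-summer
  conditions, and M₂ = e^{α(1+cos)} ≥ 1 carrying all seasonal variation.
* **Counterfactual life expectancy**: e₆₀ = ∫ t f(t) dt with
  f(t) = λ(t)e^{−∫λ}, integrated numerically once with λ = M₁M₂ and once with
  λ = M₁; the difference is the life-expectancy cost of seasonality in years.

## Worked example

Simulate one 50,000-person cohort of women born 1810 with a true rate ratio
of 2.0 and a mid-February peak, then run the full analysis chain:

```python
import seasonmort as sm

scenario = sm.ScenarioConfig(
    birth_years=[1810], sexes=("female",), cohort_size=50_000, seed=42,
    trajectories={"female": {
        "mu_star": (5.2e-5, 5.2e-5), "beta_per_year": (0.088, 0.088),
        "h": (2.0, 2.0), "peak_day": (41.0, 41.0),
    }},
)
records = sm.generate_study(scenario)
counts, fit, seas, le = sm.analyze_cohort(records, 1810, "female", seed=42)
```

which prints (via the obvious f-strings):

```
included 49347 of 50000 simulated people
beta = 2.414e-04 per day  (truth 2.409e-04)
alpha = 0.354        (truth 0.369)
rate ratio h = 1.94  95% CI [1.89, 1.99]  (truth 2.00)
peak day = 40  (truth 41, mid-February)
e60 observed    = 72.59 years
e60 model       = 72.59 years
e60 lower bound = 75.43 years
seasonality cost = 2.84 years of life expectancy
```

Reading: people dying before January 1 of the year of their 60th birthday
are excluded by the inclusion rule (49,347 remain); the fitted hazard
recovers the generating parameters; winter mortality is about twice summer
mortality; the model's mean age at death matches the cohort's observed mean
to a hundredth of a year; and had the favourable late-summer rates prevailed
year-round, this cohort would have lived 2.8 years longer on average.

The same chain is available from the shell:

```bash
seasonmort simulate --out people.csv --seed 1
seasonmort fit --input people.csv --out results/ --seed 1 --plots
seasonmort report --input results/
```

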