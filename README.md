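# lifegain

Survey-weighted hazard ratios, hazard-ratio-partitioned period life tables,
and Arriaga decomposition of life-expectancy differences — applied to the
association between daily coffee consumption and remaining life expectancy
at age 50.

## The problem

Cohort studies usually summarize an exposure's association with mortality as
a hazard ratio. Life expectancy is a more interpretable scale: *how many
years* does a 50-year-old in the exposed group stand to gain? `lifegain`
turns covariate-adjusted hazard ratios into group-specific period life
tables and decomposes the resulting life-expectancy differences by age and
cause of death. It is aimed at epidemiologists working with NHANES-style
national survey cohorts linked to mortality follow-up, and ships a
synthetic-cohort generator with the same statistical structure (five
coffee-exposure groups derived from two 24-hour dietary recalls,
heterogeneous dietary sampling weights, three competing causes of death,
right censoring), so that the full pipeline is testable without any
restricted data.

## The method

Three estimates combine into exposure-group life tables over ages 50–100:

1. **National mortality rates** m(x) by single year of age (all-cause, CVD,
   cancer), with cause-specific rates beyond the last observed age (84)
   projected by Poisson regression on age and age², log m_c(x) = b₀ + b₁x + b₂x²;
2. **Adjusted hazard ratios** HR_g per exposure group g vs non-consumers,
   from a Cox proportional-hazards model with dietary sampling weights as
   case weights, Efron tie handling and robust (sandwich) standard errors
   — exposure groups: 0, ≤1, 1–≤2, 2–≤3, >3 cups/day (one cup = 8 oz =
   236.56 mL, averaged over the available recall days);
3. **Group prevalences** p_g(x), survey-weighted by 5-year age band.

At each age the reference-group hazard solves the partition identity

    m_ref(x) = m(x) / Σ_g p_g(x)·HR_g ,    m_g(x) = HR_g·m_ref(x),

so that the prevalence-weighted mean of group hazards reproduces the
national rates exactly. Standard period life tables (q = 1 − e^(−m), radix
100 000 at age 50, mid-interval deaths, constant-hazard closure of the open
terminal age) yield e₅₀ per group; the **life gain** of group g is
e₅₀(g) − e₅₀(none). Percentile confidence intervals come from Monte Carlo
resampling of the log hazard ratios (1000 runs), and the **Arriaga
decomposition** splits each gain exactly into single-year-of-age
contributions, further allocated to causes of death in proportion to the
cause-specific rate differences.

The Cox layer also provides linear/quadratic trend tests on the ordinal
exposure code, restricted-cubic-spline dose–response curves on continuous
cups, scaled-Schoenfeld proportional-hazards diagnostics, and stratified
estimates with joint Wald interaction tests.

## Worked example

```python
import lifegain as lg

config = lg.RunConfig(
    outdir="demo_run",
    simulation=lg.SimulationConfig(n_participants=20_000, seed=7),
    exposure_source="true",   # bypass recall noise: estimate planted effects
    mc_runs=1000,
    seed=7,
)
run = lg.run_pipeline(config)
print(lg.summarize(run))
```

prints

```
lifegain run: demo_run
seed: 7    eligible participants: 19533
==============================================================
group            e50            95% CI    gain          95% CI
none           30.79    (30.47, 31.12)    0.00    (0.00, 0.00)
low            31.73    (30.51, 32.92)    0.94   (-0.43, 2.25)
moderate       32.66    (31.68, 33.69)    1.87    (0.74, 3.05)
high           32.09    (30.86, 33.24)    1.29   (-0.04, 2.57)
very_high      32.60    (31.53, 33.68)    1.81    (0.57, 3.04)
--------------------------------------------------------------
gain high: cvd +0.868y (67.0%), cancer +0.007y (0.5%), other +0.421y (32.5%)
gain low: cvd -0.032y (-3.4%), cancer +0.240y (25.6%), other +0.729y (77.8%)
gain moderate: cvd +0.552y (29.5%), cancer -0.093y (-5.0%), other +1.413y (75.5%)
gain very_high: cvd +1.132y (62.7%), cancer -0.123y (-6.8%), other +0.797y (44.1%)
```

Reading the table: under this synthetic cohort's data-generating effects,
non-consumers have 30.79 remaining years at age 50; moderate consumers
(1–≤2 cups/day) gain 1.87 years (95% MC CI 0.74–3.05), about 30% of it
attributable to reduced CVD mortality. The same objects are available
programmatically: `WeightedCoxModel(...).fit()` returns hazard-ratio
estimates with trend tests and PH diagnostics, and
`LifeExpectancyModel(rates, hazards, prevalence).fit()` returns life
tables, gains with intervals, and `.decompose(group)` tables.

A command-line interface mirrors the stages:

```sh
lifegain simulate --n 20000 --seed 7 --out cohort.csv
lifegain derive-exposure cohort.csv
lifegain run-all --n 20000 --seed 7 --outdir demo_run
lifegain report demo_run
```

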