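# Methods

## Overview

`lifegain` estimates the life-expectancy consequences of an ordered
exposure (daily coffee consumption in five groups) from three inputs: a
national mortality-rate schedule, covariate-adjusted group hazard ratios
from a survey-weighted Cox model, and the survey-weighted prevalence of the
groups by age band. The chain is: exposure derivation → eligibility
cascade → weighted Cox → rate preparation → hazard-ratio partition →
period life tables → life gains with Monte Carlo intervals → Arriaga
age-by-cause decomposition.

## Exposure derivation

Coffee volumes are standardized to 8-oz cups (236.56 mL per cup). When a
participant completed two 24-hour recalls the cup counts are averaged;
single-recall participants are used as recorded. Groups are 0 cups
(reference), (0, 1], (1, 2], (2, 3], and > 3 cups/day — intervals left-open
and right-closed, so 2.0 cups is "moderate". Subtype flags (caffeinated,
instant, with sugar) derive from item attributes; "with sugar" means total
added sugar strictly greater than 0 g. Mixed consumers (e.g. caffeinated
and decaf items in one day) are classified by the *any-item* rule by
default; a volume-majority rule is available via
`subtype_flags(..., mixed_rule="majority")`, since either convention is
defensible and the choice is not settled by the data structure itself.

The eligibility cascade removes, in fixed order: pregnant participants,
then records missing mortality linkage, smoking, education, marital status,
and physical activity. A record failing several criteria is counted at the
first applicable step, so step counts sum to the total removed. Family
income is *not* an exclusion: missing income-to-poverty ratios form their
own category (low ≤ 1.30 < moderate ≤ 3.50 < high), because income
missingness is too common to drop. Sufficient physical activity is ≥ 150
weekly minutes of moderate activity, ≥ 75 vigorous, or an equivalent
combination (1 vigorous minute = 2 moderate minutes).

## Hazard model

Cox proportional hazards on time since interview (time-on-study), with age
at interview as a covariate; dietary sampling weights enter as case
weights; ties are handled by Efron's method; exposure enters as four
indicators against the non-consumer reference. Cause-specific hazards
(CVD, cancer) censor deaths from competing causes at the event time.
Standard errors are robust: the Lin–Wei sandwich computed from vectorized
score residuals (risk-set sums via cumulative sums; Breslow convention
inside the residuals — the Efron correction to residuals is negligible at
monthly tie density and is not applied). A unit test cross-checks this
sandwich against an independent reference implementation. Weights-only
variance is a deliberate simplification: survey design variables
(strata/PSUs) are out of scope, so the sandwich accounts for weighting and
model misspecification but not for cluster sampling.

Trend tests enter the ordinal group code (0–4) as a continuous term
(linear) and add its square (nonlinear); a nonlinear trend is declared when
the quadratic term's Wald p < 0.05 regardless of the linear p. The
dose–response curve uses a restricted cubic spline of continuous cups
(Harrell truncated-power basis; default 3 knots at the 10th/50th/90th
weighted percentiles among consumers), anchored at HR = 1 for 0 cups, with
a joint Wald test of the nonlinear basis terms. Proportional hazards are
checked per term by the scaled-Schoenfeld correlation-with-time test; the
reported global statistic is the sum of per-term chi-squares (df = number
of terms), an approximation that ignores cross-term residual correlation.
Stratified analyses refit within strata (the "other" race category is
excluded from race subgroups); interaction p-values are joint Wald tests of
exposure-by-stratum product terms in the pooled model. Subtype strata
(caffeinated/instant/sugar) are defined among consumers with non-consumers
shared as reference, so no pooled interaction test is computed there.

If a non-reference group has no events for the requested cause its
indicator is not estimable; the group is retained in the output flagged
non-identifiable rather than silently dropped.

## Rate preparation

Rate tables carry all-cause, CVD and cancer central death rates per
person-year by single year of age (optionally by sex/race). Cause-specific
rates beyond the last observed age (default 84) are projected by Poisson
regression of the observed rates on age and age² with a log link
(unit-exposure offset, since death/population counts are not carried);
fitted over at least 10 contiguous ages, and exact when the input is itself
log-quadratic. All-cause rates are never re-projected; where projected
cause rates would exceed the all-cause rate, the all-cause rate is raised
to the cause sum with a logged warning. By default only CVD is projected
(its national series is the one that stops early); any cause subset can be
requested.

## Life tables and partition

Hazard ratios are applied on the hazard (m) scale, where proportionality
is actually stated: at each age the reference hazard is
m(x) / Σ_g p_g(x)·HR_g and group g's hazard is HR_g times that, making the
prevalence-weighted mean of group hazards reproduce the national rate to
machine precision. Five-year-band prevalences are held constant within a
band; the oldest band is carried to age 100. Cause-specific hazards are
partitioned the same way with cause-specific HRs; the residual "other"
cause is the group total minus CVD and cancer, floored at zero with a
warning (an error if the negative residual exceeds half the group total,
which indicates cause HRs inconsistent with the all-cause HR).

Life-table conventions (all configurable): one-year intervals with
q = 1 − e^(−m); radix 100 000 at age 50; deaths at mid-interval
(L = l − d/2); open terminal age closed by the constant-hazard rule
L₁₀₀ = l₁₀₀/m₁₀₀ with q₁₀₀ = 1. Hazard ratios are assumed constant over
ages 50–100 because a single HR per group is estimated.

## Uncertainty and decomposition

Monte Carlo intervals resample each group's all-cause log hazard ratio
independently from Normal(β, se²), rebuild the partitioned life tables per
draw (1000 runs by default), and report 2.5th/97.5th percentiles for each
e₅₀ and gain. Percentile (not normal-approximation) intervals are used
because e₅₀ is a nonlinear transform of the HRs. Only the HRs are
resampled; baseline rates and prevalences are treated as fixed — a
documented understatement of total uncertainty.

The Arriaga decomposition allocates e₅₀(comparison) − e₅₀(reference) to
single years of age via the direct + indirect/interaction terms, with the
standard open-age term at 100; the contributions sum to the difference
exactly (tested to 1e-9). Each age's contribution is then split across
causes in proportion to the cause-specific rate differences; at ages where
the total rates coincide (|Δm| < 1e-15) the split is undefined and set to
zero with a flag, so cause conservation holds at all non-degenerate ages.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes: ages uniform on
20–85; log-normal dietary weights renormalized to mean 1 (log-sd 0.6 —
heterogeneous but stable survey-like weights); five exposure groups with
default shares (0.45, 0.12, 0.17, 0.12, 0.14), i.e. slightly over half
consuming coffee; cups uniform within each bounded category with a
unit-mean exponential tail above 3 cups (the within-category distribution
is an assumption, not data-derived); two recalls with additive Gaussian
noise truncated at zero for consumers and exact zeros for non-consumers,
the second recall present for 67% of participants. The default noise SD
(1.30 cups) was calibrated once with `calibrate_recall_noise` so the
weighted between-recall correlation is ≈ 0.74 at n = 30 000; the helper
re-finds it by root-bracketing since the correlation is monotone in the
noise SD.

Mortality uses latent competing cause-specific times: Gompertz baseline on
attained age (rate 0.004/person-year at age 50, log-slope 0.085/year —
adult all-cause mortality of a high-income population), split across
CVD/cancer/other as 0.31/0.23/0.46, multiplied by the group- and
cause-specific hazard ratios and by covariate effects (male +0.35, current
smoking +0.45, former +0.15 on the log scale); the minimum latent time
wins. Default planted hazard ratios give CVD a protective U-ish gradient
(0.90/0.82/0.80/0.73 across consumption groups), cancer none, and "other"
a gradient chosen so the implied all-cause HRs are ≈ 0.93/0.81/0.87/0.87 —
an association profile of the shape reported for coffee in U.S. cohorts.
Censoring combines staggered administrative follow-up (uniform 0.5–19
years, mirroring rolling enrollment with a fixed linkage date) with a small
exponential loss-to-follow-up hazard (0.001/person-year); follow-up is
recorded at month precision, as mortality linkage files do. Exclusion
flags are drawn at the observed cascade's marginal frequencies.

What the generator does *not* emulate: survey strata/PSUs and within-PSU
correlation, item-level food codes (subtype flags are drawn directly),
secular trends in rates, covariate–exposure confounding (covariates are
independent of the exposure group), and exposure misclassification feeding
back into the hazard (effects act on the latent group). Consequently,
passing tests demonstrate internal statistical correctness of the
estimators under the assumed structure — not robustness to design effects
or confounding in real survey data. When the exposure is derived from the
noisy recalls rather than the latent group, fitted hazard ratios attenuate
toward 1, exactly as classical measurement error predicts; the acceptance
script reports both variants.

## Problem sizes and numerical choices

The test suite runs replicate-based checks at the sizes the properties
require: hazard-ratio recovery and CI calibration use 200 cohorts of
n = 20 000 (≥ 1 500 deaths each); pipeline-level interval coverage uses 200
studies of n = 4 000 with 250-run Monte Carlo intervals; structural
identities use 100 random input draws. The acceptance script runs one full
pipeline at n = 44 501 with 1000 Monte Carlo runs. Poisson projections use
IRLS to tolerance 1e-12; partition and conservation identities are
asserted at 1e-12 and 1e-9 respectively; spline curves are evaluated on a
101-point grid to the 99th weighted percentile of cups.

## Known limitations

- Variance ignores survey design (clusters/strata) and treats rates and
  prevalences as known; intervals are therefore somewhat narrow.
- The time scale is time-on-study with baseline age as a covariate, not
  attained age; with strongly age-varying effects the two differ.
- Proportional hazards and age-constant HRs from 50 to 100 are assumptions;
  the Schoenfeld diagnostics test the former only on the follow-up window.
- The global PH statistic is a sum-of-chi-squares approximation.
- Cause-specific hazards censor competing events (cause-specific, not
  subdistribution, hazards); cumulative-incidence statements are out of
  scope.
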