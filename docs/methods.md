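# Methods

## Exposure definitions

Raw survey responses are collapsed into the categorical exposures used in
the cost models. All range categories are left-closed/right-open and
"≥"/"≤" thresholds inclusive; any missing raw field needed by a rule
yields the explicit category `missing`, which is retained as a modelling
level rather than dropping the respondent.

* **Smoking** — heavy: current daily smoker at ≥20 cigarettes/day; light:
  current daily <20/day or current occasional with ≥100 lifetime
  cigarettes; former heavy/light use the former daily amount with the same
  20/day threshold; non-smoker: never smoker or occasional with <100
  lifetime cigarettes.
* **Alcohol** — heavy: bingeing (five or more drinks on a day in the
  previous week, or weekly bingeing in the previous month — either
  indicator true counts) or more than 21 (men) / 14 (women) drinks per
  week; moderate: at-or-below threshold, no bingeing, drank in the last 12
  months; non-drinker: no alcohol in 12 months.
* **Diet** — index on 0–10: start at 2 points, plus one point per average
  daily fruit/vegetable serving capped at 8 extra points (fractional
  servings accrue fractional points before the cap), minus 2 points each
  for >1 fruit-juice serving/day, no carrot consumption, and potato
  servings above 1/day (men) or 0.7/day (women); negative totals floored
  at 0. Categories: poor <2.5 ≤ fair <5 ≤ adequate. The per-serving point
  reading (rather than integer-only points) is the one under which the
  stated maximum of 10 is attained smoothly; it is frozen here as the
  package's convention.
* **Physical activity** — MET-hours/day = Σ (sessions/week ÷ 7) × hours
  per session × MET value, using the low-intensity MET value of each
  activity; inactive <1.5 ≤ moderately active <3 ≤ active.
* **Deprivation** — material × social quintiles of the area deprivation
  index cross-tabulated into 25 cells; both quintiles in {1,2} → low
  (4 cells), both in {4,5} → high (4 cells), otherwise moderate (17).

## Cost models

For each sex and sector (hospital, drugs, community care), total cost over
follow-up `Y_i` (rounded to whole dollars so the negative-binomial count
likelihood is well defined; rounding at $1 granularity is the
least-distorting choice) follows NB2:

    Y_i ~ NB(μ_i, α),   log μ_i = x_i'β + log t_i,   Var = μ + α μ²

with `t_i` the person-years of follow-up, so `exp(β)` are annualized cost
ratios against the reference categories (non-smoker, moderate drinker,
adequate diet, active; lowest-cost levels for SES variables). Covariates
enter by a pre-specified nested ladder: (1) age group + the four
behaviours; (2) + immigrant status, education, marital status; (3) —
the primary attribution model — + income, home ownership, urban
residence, deprivation, ethnicity, self-perceived stress, flu
vaccination; (4) + BMI and diagnosed illness indicators (hypertension,
diabetes, heart disease, cancer, stroke, dementia); (5) + fragility. The
figure-level step labels do not enumerate variables exactly, so the
grouping follows the baseline-table variable headings; ethnicity is
placed in step 3 with the extended sociodemographics.

Coefficients are estimated by IRLS at fixed dispersion (relative deviance
tolerance 1e-8, up to 200 inner iterations, at most 100 outer updates)
alternating with a scalar profile-likelihood update of α (bounded search
on log α over [1e-6, 1e3]); the outer loop stops when α's relative update
falls below 1e-5, which is far inside its statistical uncertainty.
Dispersion is estimated per model, not shared across sectors. Dummy
columns that are constant in the estimation data (an unoccupied level)
are excluded with a log record; predicting for a level that was not
estimable raises an error naming the level.

Fits are unweighted by default: the survey weights enter at the
prediction/standardization stage, where the population quantity is
formed. A configuration flag enables survey-weighted pseudo-likelihood
fitting (weights as variance weights in the same IRLS/profile loop) for
users who prefer weighted estimation throughout.

## Population attributable fractions

PAFs are computed by model-based standardization (g-computation): predict
each respondent's expected annual cost under observed exposures and again
after recoding the target exposure(s) to the reference category, pool the
survey-weighted predictions of the sex-specific models across sexes, and
take the relative difference. Conventions:

* Missing exposure levels are never recoded — an unknown exposure is not
  asserted to be unexposed.
* The alcohol counterfactual recodes both heavy drinkers and non-drinkers
  to moderate (the reference level), which can produce negative
  components when non-drinkers are costlier than moderate drinkers; a
  switch restricts recoding to heavy drinkers only.
* Province-level PAFs pool both sexes' predictions before the ratio
  rather than averaging sex-specific PAFs.
* Cycle PAFs are anchored to the first fiscal year of each cycle's field
  period; intervening years take the arithmetic mean of the nearest
  preceding and succeeding cycle estimates (nearest-cycle reading, which
  coincides with adjacent-year averaging for biennial cycles). No
  extrapolation outside the covered span.

## Burden accounting

Nominal annual sector expenditures are inflated to 2014 CAD with the
general CPI exactly once — expenditure tables carry a currency-year tag
and re-inflation is refused. Attributable dollars are PAF × expenditure
per (risk, sector, fiscal year); the 'other' sector (system operating and
capital costs outside the three person-level sectors) carries the
community-care PAF. Avoided costs hold the non-attributable budget fixed:
`C_t = B_t (1 − PAF_t)/(1 − PAF₀)`, avoided(t) = `C_t − B_t` — the only
reading under which "the baseline PAF did not change" pins down a
counterfactual budget from observed spending. The baseline PAF is the
budget-weighted all-sector PAF by default (sector-wise available via
config). Per-risk avoided costs run the same formula on each risk's own
PAF series; their overlap with the combined series is reported, not
forced to add up. Shares are reported to integer percent.

## Sensitivity analyses

* **Ladder bounds** — the step-1 (age + behaviours) and step-5
  (over-adjusted) PAFs bracket the primary step-3 estimate; the empirical
  ordering is recorded, not enforced.
* **High-cost-user trim** — the top 5% by total all-sector cost over
  follow-up (overall, not per sector) are removed — ceil(f·n) persons,
  ties broken by stable person-id order with a warning — and
  age-standardized cost ratios are compared before/after. The standard
  population is the survey-weighted age distribution of the full two-sex
  cohort; age groups lacking an exposed or reference stratum are dropped
  from numerator and denominator symmetrically with a warning.
* **IPW** — a multinomial logistic propensity model for the observed
  exposure level given the primary-attribution covariates (plus extended
  household/region covariates when present) yields stabilized weights
  (marginal level probability over fitted propensity), truncated at the
  99th percentile by default; weighted mean annualized costs per level are
  compared with the reference level. Under correct specification these
  ratios agree with the regression cost ratios.

## Synthetic cohort generator

The generator emulates the structure the analysis needs: biennial survey
cycles 2003–2013 (default 20,000 respondents per cycle; the first three
cycles form the cost-linked fitting cohort), a 14-group age distribution
(25–29 through 90+), lognormal survey weights, follow-up of 1–4 years
(80% with the full four years), behaviour prevalences drifting linearly
across cycles — heavy smoking declines from 11% to 6% — and SES
confounding introduced by tilting risky behaviour levels' log-odds by
education group (strength 0.3 by default). Raw responses (cigarette
counts, weekly drinks, servings, activity sessions, quintile pairs) are
synthesized from the sampled category so that the scoring rules recover
it exactly; missingness (1–4% by behaviour) blanks the raw fields.
Sector costs are NB2 draws from a log-link model with known coefficients
(e.g. heavy smoking raises annual hospital costs by `e^0.40`; a
non-drinker J-curve; age gradients per sector; modest education and
deprivation effects), independent across sectors given covariates —
the simplest model consistent with sector-wise fitting.

Ground-truth PAFs are computed by exact enumeration over the discrete
joint covariate distribution (age × education × deprivation × the four
behaviours, conditionally on education), including the effect of
injected missingness on the counterfactual (a missing exposure keeps its
generating level). Expected sector budgets scale the enumerated mean
annual cost to a configured represented population, with the 'other'
sector a fixed share of the total; budget tables are published in
nominal dollars against a constant-inflation CPI series (1.8%/year, base
2014) so the burden stage must perform the inflation.

Dispersion defaults (α = 1.2 / 0.9 / 0.7 for hospital/drugs/community)
are calibrated so that the package's recovery checks are informative at
their stated sample sizes: the combined-PAF estimator is unbiased, and at
these values its sampling SD at n = 20,000 is well below the 0.015
tolerance the checks assert, while the implied cost skew (CV ≈ 0.8–1.1)
remains in the plausible range for multi-year aggregated person-level
costs. Recovery of the combined PAF is assessed on the mean over ten
replicate cohorts — the usual simulation-study convention — since any
single replicate is dominated by one model-noise draw.

What the generator does **not** emulate: the survey's complex sampling
design (strata, clusters, replicate weights), linkage error, cross-sector
cost correlation, within-person cost trajectories, and real Ontario
dollar levels. Passing tests therefore demonstrate the correctness of
the estimators under a known data-generating process, not agreement with
the restricted linked data; the real analysis would additionally face
design-based variance, reporting bias in self-reported behaviours, and
administrative costing error.

## Known limitations

* NB fits use a single-equation mean model; two-part (zero-inflated)
  cost models and design-based (bootstrap replicate weight) variance
  estimation are out of scope.
* PAF uncertainty is characterized by the ladder bounds, not sampling
  CIs.
* The diet index covers fruit/vegetable quality only (no sodium, trans
  fats or energy intake), and leisure-time activity excludes transport
  and occupational activity — both inherit the source instruments'
  limitations.
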