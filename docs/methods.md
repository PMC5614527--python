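# Methods

This note documents the statistical models behind `trialcea`, the defaults
and why they were chosen, what the synthetic-trial generator does and does
not emulate, and the numerical conventions used throughout.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design assumed

A three-arm individually randomised trial (1:1:1) in peri- and
postmenopausal women with frequent vasomotor symptoms: a control arm, an
exercise intervention delivered through community social-support groups,
and an exercise intervention prompted by a DVD.  Resource use and
health-related quality of life are collected by postal questionnaire at 6
and 12 months post-randomisation; utilities are additionally measured at
baseline.  Analyses are intention-to-treat over a 12-month horizon, so no
discounting is applied to costs or outcomes.

## Costing

Costs are micro-costed per woman and per 6-month recall period as
Σ countᵢ × unit-costᵢ, in GBP at 2013/14 prices.

- **NHS/PSS perspective**: GP and practice-nurse contacts (surgery and
  out-of-hours telephone), gynaecologist, counsellor/psychologist,
  physiotherapy, X-ray, and medication constants (£38 per 6 months of
  prescription medicines; £19 per 3-month HRT repeat; £8 per repeat
  prescription issued without a consultation).  Medication costing is
  collapsed to these per-period constants rather than re-deriving dosage
  regimens, which are not available.  Hospital admissions are excluded
  from both perspectives (unrelated to the condition).  Intervention
  development-and-delivery constants (default £0 control, £37 social
  support, £78 DVD) are added once, in the first period, because delivery
  occurs during months 0–6.
- **Societal perspective**: the NHS/PSS component multiplied by (1 + VAT)
  plus productivity losses, private complementary therapies (£51 per
  contact) and out-of-pocket spending.  Paid work time lost is valued by
  the human capital approach at gross daily wages (£93 full-time, £67
  part-time; £0 when not in paid employment); unpaid (housekeeping) time
  by the proxy good approach at £8/hour.

**VAT direction and rate.**  The source analysis states that NHS/PSS costs
were VAT-adjusted in the societal perspective but not the direction or
rate.  This package *multiplies the NHS/PSS component by (1 + VAT)* with a
default rate of **0.20** (the UK standard rate in 2013/14).  Both the rate
and the per-arm intervention constants are configurable; users who need a
different convention should override `vat_rate` in the run config.  This
is the single most consequential undocumented convention in the costing
stage — flagged here deliberately.

Totals are reported to 2 decimal places and the breakdown components sum
exactly to the totals (property-tested over random records).

## Utilities and QALYs

SF-12 responses are classified into the six-dimension SF-6D state
(physical functioning, role limitation, social functioning, pain, mental
health, vitality) by a rule table (CSV: `dimension, level, item,
responses`; per dimension the highest matching level wins, level 1 is the
default).  States are scored as

    utility = intercept + Σ decrement(dimension, level) [+ most-severe term]

with a tariff CSV (`dimension, level, decrement`; special rows `intercept`,
`most_severe`, `floor`).  The published UK standard-gamble weights (index
range 0.345–1) are **not shipped** — they are licensed survey scoring
coefficients printed elsewhere, and inventing numbers would be worse than
requiring a file.  The test suite uses a synthetic toy tariff; whether a
given study scored SF-6D with original or revised weights is the user's
responsibility via the tariff file.

QALYs are the area under the piecewise-linear utility–time curve through
the assessments at 0, 0.5 and 1.0 years (trapezoid rule), the standard
convention in trial-based evaluations and the only rule consistent with
period arithmetic such as ½ × 0.5 × (0.704 + 0.716) = 0.355.  The horizon
must coincide with an assessment (0.5 or 1.0 years) and utilities inside
it must be complete — imputation runs first.  Negative utilities are not
modelled (the SF-6D floor is positive).

## Missing data

Questionnaire nonresponse makes whole follow-up waves missing, so
imputation operates at the level of **period totals** (period NHS/PSS and
societal costs, utility at 6 and 12 months), not individual resource
items.  The imputation model for each incomplete variable is a linear
regression on

1. baseline covariates selected by stepwise regression from: age, BMI
   class, menopause status, antidepressant/HRT use, baseline symptom
   frequency, randomised arm, baseline utility — retention threshold
   **p ≤ 0.30** (deliberately liberal: imputation models should be
   inclusive), and
2. the other imputable variables (current filled values), which is what
   makes the equations "chained" and lets the imputation exploit
   within-woman correlation between costs and utilities across waves.

Each cycle draws the regression parameters from their posterior under the
standard noninformative prior (σ² from a scaled inverse-χ², β from a
normal around the least-squares fit) and imputes every missing cell by
**predictive mean matching**: the observed value of a donor drawn uniformly
from the k nearest observed rows by predicted mean (predictions for
observed rows use the posterior mode, for missing rows the parameter draw
— "type-1" matching, the convention in mainstream MI software).  PMM
guarantees imputed utilities stay in [0, 1] and imputed costs non-negative
because donors are observed values.

Defaults: **M = 10** imputed datasets (as in the motivating analysis),
**k = 5** donors and **10 cycles** per dataset (conventional defaults; the
source is silent), backward stepwise direction (deterministic; forward
available).  Pooling follows Rubin's rules: point = mean of estimates,
T = W + (1 + 1/M)·B, degrees of freedom by the classic large-sample
formula; 95% CIs use normal quantiles on √T, matching the symmetric
intervals of the motivating report.

## Incremental analysis

Adjusted arm differences come from OLS of the outcome on arm indicators
plus covariates, with heteroskedasticity-consistent **HC1** sandwich
standard errors (cost data are right-skewed; HC1 matches the common
default of mainstream econometric software; HC0–HC3 configurable).
Default adjusters — costs: age, BMI class, menopause status, baseline
symptom frequency; QALYs additionally: baseline utility, inpatient stays,
employment status, change in antidepressant/HRT use, change in symptom
frequency.

Joint uncertainty: a nonparametric bootstrap stratified by arm (preserving
the 1:1:1 allocation), refitting both outcome regressions per resample so
cost and QALY increments stay paired.  With M imputed datasets the B
(default **5,000**) replicates are spread evenly across datasets (B/M
each, remainder to the first datasets, logged) and the clouds stacked —
the simplest scheme that propagates both sampling and imputation
uncertainty.  Covariates for the bootstrap regressions are
stepwise-selected (p ≤ 0.30, arm forced in) once on the first completed
dataset and reused across replicates; per-replicate re-selection is
available by flag but costs ~100× more and changes little in randomised
data.

Decision outputs:

- **ICER** = ΔC/ΔE only in the trade-off quadrant (ΔC > 0, ΔE > 0);
  cheaper-and-more-effective is *dominant*, dearer-and-less-effective
  *dominated*; the cheaper-but-less-effective (southwest) quadrant reports
  the ratio with an explicit flag since it is a willingness-to-accept.  A
  bare negative ratio is never printed.  ICERs are computed from
  full-precision internal estimates; recomputing them from rounded summary
  output will not reproduce them exactly (e.g. 52/0.006 = 8,667 from a
  table whose unrounded inputs give a visibly different ratio).
- **CEAC(λ)** = fraction of replicates with λ·ΔE − ΔC > 0, on a WTP grid
  of £0–£50,000 in £500 steps (bracketing the UK £20,000–£30,000 band).
- **CEAF**: at each λ the optimal strategy maximises *expected* NMB across
  strategies (comparator at 0); the frontier probability is the fraction
  of replicates in which that strategy attains the per-replicate maximum.
  All strategies share resamples, which the frontier requires.
- **Complete-case companion**: participants with any missing analysed
  field for a timepoint are dropped; adjusted differences get **BCa**
  intervals from 1,000 stratified resamples (bias correction z₀ from the
  replicate distribution, acceleration from the leave-one-out jackknife).
  A degenerate replicate distribution collapses to a point interval.

## The synthetic-trial generator

The generator produces tables with the statistical shell the analysis
assumes; its defaults *are* the study conditions:

- 3 arms × 87 women; age ~ N(52, 2.5²) clipped to 48–57; 70%
  postmenopausal; BMI classes 33/40/27% normal/overweight/obese; ~9
  vasomotor episodes/day at baseline; employment 40/25/35%
  full-time/part-time/not employed.
- Utilities: per-arm mean at each assessment + a woman-level random
  intercept (SD 0.10) + occasion noise (SD 0.08), truncated to [0, 1]
  (total SD ≈ 0.13, matching an SE of 0.014 at n = 87).  The default arm
  means reproduce the published raw means, including the baseline
  imbalance (control 0.704, social support 0.694, DVD 0.662).
- Resource counts: negative binomial (gamma–Poisson, shape 0.8) around a
  fixed contact-mix profile scaled per arm/period to hit the published
  period cost means net of intervention constants — questionnaire resource
  use in this population is sparse and overdispersed.
- Societal extras are concentrated in the control arm's second period
  (mean 6 unpaid hours lost), reproducing the published sign flip of the
  12-month societal comparison.
- Dropout: monotone by default (a 6-month nonresponder stays missing at
  12 months; configurable), marginal rates 7%/15%, MAR via a logistic
  model on observed baseline covariates (+0.3 log-odds per SD of age,
  −0.8 per SD of baseline utility; intercept solved numerically so the
  marginal rates are hit on the realised sample).  MCAR mode for tests.
- An optional `cost_utility_corr` knob couples the utility intercept into
  a resource-use frailty so sicker women consume more care; the default is
  0 because no individual-level cost–utility correlation is published.

**What passing tests do not show about real data.**  The generator is
Gaussian/negative-binomial with a single random intercept: real
questionnaire costs have heavier tails and structural zeros, real utility
trajectories are not exchangeable around an intercept, real dropout is at
best approximately MAR, and true effects are unknown.  Parameter-recovery
results (unbiasedness, CI coverage) certify the *estimation machinery*
under the stated data-generating process, not the substantive published
findings.  Note also that with QALY differences of ~0.01 and n = 87 per
arm, the sign of an adjusted QALY difference in any single synthetic
realisation is sampling noise; only probability statements (CEAC/CEAF) are
stable at this scale.

## Numerical conventions and edge cases

- All randomness flows from integer seeds through
  `numpy.random.SeedSequence` spawning; identical configs give
  byte-identical output bundles (CSVs are written with fixed 6-decimal
  formatting and a provenance comment line).
- Stepwise selection uses grouped partial-F tests (categorical covariates
  tested jointly); p-value ties drop the later candidate; exactly
  collinear candidates are pre-filtered by incremental rank so the earlier
  one in the supplied order wins.
- In PMM, posterior covariance factors use an eigendecomposition of the
  pseudo-inverse, so rank-deficient imputation designs degrade gracefully.
- ΔE = 0 yields an explicitly *undefined* ICER label, never a division
  error; empty complete-case sets and unknown categories/mechanisms raise
  errors naming the offending field.
- BCa clips the bias-correction proportion to [1/2B, 1 − 1/2B] to avoid
  infinite z₀ in extreme clouds.

## Validation problem sizes

The test suite validates: trapezoid QALYs against dense numerical
integration (1,000 random trajectories, <1e-10); Rubin pooling against
hand arithmetic and a 10,000-input variance-ordering sweep; sandwich SEs
against explicit matrix algebra (6-row fixture) and classical OLS under
homoskedasticity (n = 5,000, within 5%); CEAC against its Gaussian closed
form (B = 5,000, 3 Monte-Carlo SEs); CEAF against exhaustive enumeration
on toy clouds; PMM under MCAR (n ≈ 2,000); and the full pipeline on 200
simulated trials of 3 × 87 with true ΔC = £50 and ΔE = 0.01 — unbiased
within Monte-Carlo error, ≥93% CI coverage, and mean CEAC at the true
ICER (£5,000/QALY) of 0.5.  The per-trial CEAC at the true ICER is
asymptotically Uniform(0, 1) — the pivot ΔNMB̂/SE is standard normal
whenever the true net benefit is zero, at any n — so the 0.5 property is a
property of the *average* over trials, and that is what is tested.  These
sizes keep the whole suite around five minutes on one CPU while leaving
every Monte-Carlo tolerance at 3 standard errors.

## Known limitations

- No MNAR sensitivity analyses (pattern-mixture/delta adjustment), no
  friction-cost productivity method, no discounting utilities, no EQ-5D,
  no value-of-information or decision-analytic modelling.
- The Barnard–Rubin small-sample degrees-of-freedom correction is offered
  only through the pooled `df` field; CIs use normal quantiles.
- SF-12→SF-6D mapping is rule-table-driven; the package validates
  structure, not the clinical content of a supplied mapping.
- The human capital approach tends to overestimate productivity losses;
  the societal perspective inherits that property by construction.
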