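# trialcea

Trial-based cost-utility analysis in Python: from participant-level
resource-use questionnaires and SF-12-derived utilities to
perspective-specific costs, QALYs, multiply-imputed and
regression-adjusted incremental estimates, bootstrap uncertainty clouds,
ICERs, and cost-effectiveness acceptability frontiers.

## Who this is for

Health economists running within-trial economic evaluations — in
particular three-arm pragmatic trials where two interventions are compared
against a control on cost per quality-adjusted life-year (QALY).  The
package grew out of an evaluation of exercise interventions for vasomotor
menopausal symptoms (a community social-support exercise programme and a
DVD-prompted programme vs an exercise-consultation control, 87 women per
arm, follow-up questionnaires at 6 and 12 months), and a synthetic-trial
generator reproduces that study's statistical shell so the whole pipeline
is testable without access to any participant data.

## What it computes

- **Costs.** Resource-use counts are valued against a unit-cost table
  (GBP 2013/14 defaults included).  The NHS/PSS perspective covers
  primary/secondary-care contacts and prescriptions plus per-arm
  micro-costed intervention constants; the societal perspective adds
  productivity losses (human-capital approach for paid work at £93/£67 per
  full-/part-time day; proxy-good approach at £8 per hour of unpaid work),
  private therapies, out-of-pocket spending, and a VAT adjustment of the
  NHS/PSS component.  Nothing is discounted over the 12-month horizon.
- **Utilities and QALYs.** SF-12 responses map onto the SF-6D
  classification and are scored with a user-supplied standard-gamble
  tariff (the published UK weights are not redistributed); QALYs are the
  area under the piecewise-linear utility–time curve,
  `QALY = Σ ½(uₜ + uₜ₊₁)Δt`.
- **Missing data.** Multiple imputation of period costs and utility scores
  by chained equations with predictive mean matching (M = 10, donor pool
  k = 5), imputation-model covariates chosen by stepwise regression with a
  p ≤ 0.30 retention threshold; estimates pooled by Rubin's rules,
  `T = W + (1 + 1/M)·B`.
- **Incremental analysis.** Arm differences in mean cost and QALYs from
  multiple linear regression with Huber–White (HC1) sandwich standard
  errors; a 5,000-replicate arm-stratified nonparametric bootstrap spread
  across the imputed datasets yields the joint (ΔC, ΔE) cloud; ICER
  ΔC/ΔE with dominance classification; cost-effectiveness acceptability
  curves `CEAC(λ) = P(λ·ΔE − ΔC > 0)` and frontiers (probability that the
  strategy maximising expected net monetary benefit is cost-effective);
  complete-case companion analysis with bias-corrected and accelerated
  (BCa) bootstrap intervals.

## Worked example

```bash
trialcea demo --seed 1 --outdir results/demo
```

synthesizes the default trial (3 × 87 women, ~7%/15% questionnaire loss
missing at random), imputes, and runs both perspectives at both
timepoints.  It prints the incremental summary:

```
perspective timepoint        comparison  delta_cost  cost_ci_low  cost_ci_high  delta_qaly  qaly_ci_low  qaly_ci_high        icer  decision
    nhs_pss        6m    dvd_vs_control   63.437361    49.713350     77.161373   -0.004398    -0.013363      0.004567         NaN dominated
    nhs_pss        6m social_vs_control   61.311797    42.811710     79.811885   -0.001415    -0.009106      0.006277         NaN dominated
   societal        6m    dvd_vs_control   68.634546    52.148927     85.120164   -0.004398    -0.013363      0.004567         NaN dominated
   societal        6m social_vs_control   66.204149    44.146483     88.261815   -0.001415    -0.009106      0.006277         NaN dominated
    nhs_pss       12m    dvd_vs_control   34.387624    13.819837     54.955410   -0.006171    -0.029553      0.017211         NaN dominated
    nhs_pss       12m social_vs_control   26.212418     4.063028     48.361807   -0.003215    -0.023541      0.017110         NaN dominated
   societal       12m    dvd_vs_control   -6.000867   -34.217683     22.215949   -0.006171    -0.029553      0.017211  972.428169 southwest
   societal       12m social_vs_control  -31.907028   -59.665166     -4.148890   -0.003215    -0.023541      0.017110 9923.578916 southwest
```

Reading it: at 6 months both exercise arms cost more than control
(delivery costs dominate — the intervention constants are £37 and £78 per
woman) and, on this random realisation, gain slightly fewer QALYs, so both
are *dominated*.  At 12 months from the societal perspective the control
arm's accumulated productivity losses make the social-support arm £32
cheaper per woman; with a (noisy) negative QALY difference that lands in
the *southwest* quadrant, where the ratio is a willingness-to-accept, not
an ICER.  QALY differences in this population are genuinely on the 0.01
scale, so at n = 87 per arm their sign is sampling noise — which is
exactly why the bundle also contains `ceac.csv`/`ceaf.csv` (probability
statements across willingness-to-pay values) rather than point decisions
alone.  The output directory holds `participants.csv`, a Table-2-shaped
`table2.csv` (raw arm means ± SE, adjusted differences with 95% CIs),
`incrementals.csv`, `ceac.csv`, `ceaf.csv`, `complete_case.csv`, and a
`manifest.json` carrying the seed, config hash, imputation-model summary
and per-stage row counts.  Re-running with the same seed reproduces every
file byte for byte.

The same analysis runs on real data from CSV via a YAML config
(`trialcea analyse --config run.yaml` with an `input_csv` entry), and the
stages are importable directly:

```python
from trialcea import qaly_auc, icer, pool_rubin

qaly_auc([0.704, 0.716, 0.720], horizon=1.0)   # 0.714 QALYs
icer(52, 0.006)                                 # 8666.67 GBP/QALY, trade-off
pool_rubin([1, 2, 3], [1, 1, 1]).total          # 2.333…
```

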