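# ccsst — Cross-Country Simple Segmentation Tool

`ccsst` segments older adults in aging-survey panels (SHARE-style biennial
interviews) into needs-based health states and models how populations move
between them.  It is aimed at health-services researchers and policy
analysts who want comparable, needs-based metrics across countries without
utilization data.

The toolchain has four parts:

1. **Segmentation.**  Raw survey items — self-reported physician diagnoses,
   the 12-item EURO-D depression inventory, five performance-based
   cognition tests, Fried-phenotype frailty criteria, the Global Activity
   Limitation Index (GALI) and ADL difficulty — are scored into clinical
   indicators and mapped to five ordinal *Global Impressions* (GI)
   segments: healthy ≺ chronic asymptomatic ≺ chronic symptomatic ≺ long
   course of decline ≺ limited reserve and serious exacerbation.  An
   observation qualifying for several segments takes the most severe.
   Four binary *Complicating Factors* (CFs) — caregiver dependence, absent
   social support, frequent inpatient/outpatient transitions, and
   polypharmacy (≥5 daily medications) — flag extra care complexity.

2. **Prevalence.**  Survey-weighted GI×CF composition per country-wave and
   a cross-country ranking by the population share with *high medical
   needs* (the two most severe segments).

3. **Transition modelling.**  GI collapses to a 3-state space —
   low needs ⇄ high needs → death — observed only at interview times
   (death times exactly).  Transition intensities follow a log-linear
   proportional-hazards model

   ```
   q_rs(z) = q⁰_rs · exp(β_rsᵀ z),        (r,s) ∈ {L→H, H→L, L→D, H→D}
   ```

   with covariates (country, gender, age class, any CF) piecewise-constant
   per interval.  The interval likelihood uses P(t) = exp(Qt); censored
   contacts that confirm survival without a segmentable state are
   marginalized exactly.  `exp(β)` is reported as a hazard ratio on the
   instantaneous transition risk, with Wald CIs from the observed
   information.

4. **Predictive validity.**  Cox proportional-hazards models of time to
   death (Breslow ties; adjusted for age, age², gender) contrast the most
   vs least severe baseline GI segment, and any-CF vs none, per country,
   with Kaplan–Meier curves for display.

Because the real survey microdata are access-restricted, the package ships
a synthetic-panel generator with known ground truth at both levels: raw
items that round-trip exactly through the segmentation rules, and latent
trajectories drawn from a known covariate-dependent generator by exact
event simulation.  Every analysis is therefore fully testable offline.

## Worked example

```python
from ccsst import (SimulationConfig, simulate_survey_panel, compute_indicators,
                   segment_panel, build_panel, MarkovPanelModel,
                   BUNDLED_COGNITION_REFERENCE)

cfg = SimulationConfig(n_persons=1000, seed=42)      # true CF hazard ratio = 2.0
raw, truth = simulate_survey_panel(cfg)              # raw survey items + hidden states
seg = segment_panel(compute_indicators(raw, ref=BUNDLED_COGNITION_REFERENCE))
data = build_panel(seg, covariates=["any_cf"])
res = MarkovPanelModel(data).fit()
print(res.summary())
```

```
Panel-observed 3-state Markov model (LOW <-> HIGH -> DEATH)
================================================================
persons: 1000    records: 5460
log-likelihood: -3833.324    converged: True

Baseline intensities (per year)
 transition     q0  ci_low  ci_high  se_log
  low->high 0.1163  0.1040   0.1301  0.0573
  high->low 0.1070  0.0891   0.1285  0.0934
 low->death 0.0256  0.0195   0.0337  0.1398
high->death 0.1674  0.1467   0.1910  0.0673

Hazard ratios (exp(beta), Wald 95% CI)
 transition covariate     hr  ci_low  ci_high  se_log
  low->high    any_cf 1.8215  1.5115   2.1951  0.0952
  high->low    any_cf 0.9794  0.7151   1.3412  0.1604
 low->death    any_cf 0.9660  0.5324   1.7528  0.3040
high->death    any_cf 0.8579  0.6867   1.0717  0.1136
```

Reading this: the recovered yearly baseline intensities (0.116, 0.107,
0.026, 0.167) sit close to the generating values (0.12, 0.10, 0.02, 0.15),
and the estimated hazard ratio of a complicating factor on progression into
high needs is 1.82 with 95% CI [1.51, 2.20], covering the generating value
of 2.0; the CF was given no true effect on the other three transitions and
their estimated ratios straddle 1.

The same pipeline is available from the shell:

```sh
ccsst simulate --seed 42 --n-persons 1000 --out panel.csv --truth truth.csv
ccsst segment     --in panel.csv --out segmented.csv
ccsst prevalence  --in segmented.csv --out prevalence.csv --wave 6
ccsst transitions --in segmented.csv --out hazards.csv --covariates any_cf
ccsst validate    --in segmented.csv --out validity.csv --contrast gi
```

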