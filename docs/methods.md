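# Methods

## Indicator scoring

**EURO-D.**  The depression score is the count of endorsed symptoms over
the 12-item inventory; case-level depression is a score strictly above 3
(the literature-standard caseness threshold; configurable).  When 10 or 11
items are observed the count is prorated to the 12-item metric and rounded;
with fewer than 10 observed items the score is missing.  The minimum-item
rule is configurable through `MissingPolicy`.

**Cognition.**  The composite is the mean of per-test z-scores for verbal
fluency, immediate recall, delayed recall, orientation and numeracy against
a wave-1 reference sample (per-test mean and sample SD, n−1 denominator).
Impairment is a composite *strictly* below −1.5 SD.  Any missing test makes
the composite missing — the five tests measure distinct domains and we do
not average over a partial battery.

**Frailty.**  Fried-phenotype count: frail ⇔ at least 3 of the 5 criteria
(exhaustion, weight loss, weakness, slowness, low activity).  The criteria
enter as precomputed booleans because their raw-item thresholds (grip
strength by gender and BMI, walking-speed cutoffs) are survey-specific; the
mapping from raw items to criteria is the caller's responsibility.  With
partially missing criteria the indicator is scored whenever the observed
items already decide the outcome, and missing otherwise.

**Chronic disease.**  Diagnoses are split into life-threatening (myocardial
infarction, congestive heart failure, stroke, COPD, hip fracture, cancer)
and non-life-threatening (hypertension, high cholesterol, diabetes, ulcer,
Parkinson's, cataracts, arthritis).  The arthritis indicator composites the
era-specific survey items: osteoarthritis / rheumatism / osteoporosis in
waves 1–4, rheumatoid arthritis / osteoarthritis-or-other-rheumatism from
wave 5.  Chronic diagnoses are carried forward: once reported, a condition
is present at all later waves (cumulative OR), so a missing later report
never revokes a diagnosis.

## Segment assignment

The five qualifying conditions are evaluated in three-valued (Kleene)
logic, and the most severe true condition wins.  Missingness therefore
causes non-assignment only when it is actually decisive: a frail person
with no chronic disease is assignable without a GALI response, while a
person with a chronic disease and missing GALI is not (the chronic rules
need the limitation level), and an unresolvable rule *above* the best true
rule also blocks assignment (the most-severe-wins tiebreak would be
ambiguous).  Unassigned observations carry a reason code
(`missing_data` / `no_rule`).  A complete profile can satisfy no rule —
e.g. ADL difficulty alone without chronic disease, frailty or impairment —
and is left unassigned rather than forced into a segment; this mirrors the
instrument's small residual non-assignment rate.

Depression with no activity limitation is not excluded from the healthy
rule explicitly; such profiles qualify for both healthy and chronic
asymptomatic, and most-severe-wins resolves them to the latter.

CF thresholds: polypharmacy at ≥5 daily medications; "frequent transitions
between inpatient and outpatient care" at ≥2 hospital admissions in the
last 12 months (no canonical cutoff exists; configurable).  `any_cf` uses
the same three-valued logic: true as soon as one flag is true, false only
when all four are observed false.

## Weighted prevalence

Proportions are weighted by the calibrated cross-sectional weight (1.0
when absent) and renormalized over *assigned* observations; unassigned
rows are excluded from denominators with a logged count.  Countries are
ranked ascending by the weighted share in the two most severe segments;
a country missing the target wave contributes its most recent earlier wave
instead.  Ties break lexicographically.  Proportions are invariant to
rescaling all weights, and design-based variance estimation is out of
scope.

## The 3-state transition model

States: low needs (GI 1–3), high needs (GI 4–5), death.  Transitions are
allowed in both directions between the living states and into death from
either; death is absorbing.  Intensities are log-linear in covariates,
`q_rs(z) = q⁰_rs exp(β_rsᵀ z)`, every covariate acting on all four
transitions unless constrained.  Covariates are piecewise-constant at
their value at the start of each observation interval — the convention for
time-varying covariates in interval-censored panels.

**Likelihood.**  Panel interval from observed state r to observed state s:
`P_rs(Δt; z)`.  To an exactly observed death: `Σ_k P_rk(Δt) q_{k,death}`
(alive in some state k until the death instant, then an instantaneous
death transition).  To a terminal censored-alive contact:
`Σ_k P_rk(Δt)` (survival with unknown state).  Because death is absorbing,
the full generator is block-triangular and the living-states block of
`P(t)` equals `exp(At)` for the 2×2 living sub-generator A.  This 2×2
exponential is evaluated in closed spectral form — A's discriminant
`(A₀₀−A₁₁)² + 4 q_LH q_HL` is nonnegative, so the eigenvalues are always
real — vectorized over all interval lengths, with a first-order series
fallback near coincident eigenvalues.  The public
`transition_probability` uses `scipy.linalg.expm` on the full 3×3
generator; tests cross-check the two routes to 1e−11.

A censored-alive contact *between* two informative observations adds no
information (survival to the later record already implies survival at the
contact, and the state marginalization is exact by the semigroup
property), so such records are merged into the surrounding interval
whenever the covariates are constant across the gap; when they change, the
interval is evaluated as an explicit product of per-piece propagators.
Leading censored records, which carry no transition information, are
dropped with a logged count.

**Deaths known only to an interval** (year without a date) are placed at
the midpoint between the last contact and the end of the reported
interval and treated as exact — a documented approximation, adequate when
the interval is short relative to the intensity scale.

**Estimation.**  Parameters are `log q⁰` (positivity by construction) plus
the β's.  Start values are crude rates — observed transition counts over
person-time at risk in the origin state, floored at half an event — with
β = 0.  The likelihood is maximized by BFGS with 3-point finite-difference
gradients (relative tolerance 1e−6); a stop on "precision loss" is
accepted as converged only if the score has effectively vanished, and
anything else is reported as non-convergence, never silently.  Standard
errors come from the inverse observed information (central-difference
Hessian at the optimum); hazard-ratio CIs are `exp(β̂ ± 1.96·SE)`.
Transitions with zero observed events are flagged as weakly identified.
Identical contributions are aggregated (counts per covariate pattern ×
interval length × state pair), which makes a 3000-person likelihood
evaluation a handful of 2×2 spectral decompositions plus vectorized
exponentials — a full fit takes ~0.2 s, so replicated calibration studies
are cheap.

## Survival validation

Baseline is each person's first assessable observation.  The GI contrast
keeps only persons starting in the least or most severe segment (exposure
0/1); the CF contrast uses any-CF at baseline.  Follow-up runs to death or
last contact.  Cox models (lifelines, Breslow tie convention, Newton
precision 1e−9) adjust for age at baseline, age² and gender; age is
centered before squaring to reduce collinearity, which leaves the exposure
hazard ratio unchanged.  Models are fitted per country, matching the
cross-country validity design, and countries where a group has no deaths
are reported as NaN rather than dropped.  Kaplan–Meier curves use the
product-limit estimator.

## Synthetic data

The generator emulates the *structure* of a multi-country biennial aging
panel: waves at 0, 2, …, 12 years, country/gender/age covariates, a latent
3-state process simulated exactly (Gillespie) under person-specific
intensities, states observed only at wave times, deaths at exact event
times, and interviews censored independently of state (the
non-informative-contact assumption; baseline interviews are never
censored, treating them as enrollment).

Defaults (per year): q⁰ = 0.12 (L→H), 0.10 (H→L), 0.02 (L→D), 0.15 (H→D);
15% start in high needs; 30% carry a complicating factor whose true effect
is a hazard ratio of 2.0 on progression and 1.0 elsewhere; 5% of follow-up
interviews are censored.  These magnitudes are plausible for a 50+ cohort
over 12 years (roughly a third of the cohort dies, high-needs mortality
~7× low-needs) and give every transition type ample events at n = 3000.

Raw-item rendering maps each latent state to survey items that segment
back exactly: high needs renders as a Fried-frail profile (or, for a
configurable 30% of persons, a limited-reserve profile: life-threatening
diagnosis plus severe limitation), low needs as a persistent per-person
style — healthy, chronic asymptomatic (hypertension), or chronic
symptomatic (stroke with moderate limitation) — so that diagnosis
carry-forward never contradicts the intended label.  Uninformative
contacts render with GALI, frailty and cognition all missing, which the
rule engine provably cannot assign.  Cognition scores are drawn within
±0.3 SD of a bundled synthetic reference population.

**What passing tests do and do not show.**  The generator's items are
*consistent by construction* with the scoring rules, so round-trip tests
validate the rule engine's logic, not its agreement with any real
instrument's administration.  Likewise the latent process is exactly
Markov with proportional covariate effects, so parameter-recovery and
coverage results demonstrate correctness of the estimator under its own
assumptions — not robustness to misclassification, informative attrition,
frailty heterogeneity or non-Markov dynamics, none of which the generator
emulates.  Survey weights are 1.0 throughout; calibrated-weight
construction is out of scope.

## Numerical and design choices

- Probabilities are floored at 1e−300 inside logs; an impossible observed
  transition therefore contributes −∞-like penalties that the optimizer
  moves away from, rather than crashing.
- `log q⁰ = −∞` is accepted as a structural zero (e.g. death-only
  sub-models in tests).
- The 192-cell rule grid, the 2^5 frailty patterns and the 0–12 EURO-D
  counts are tested exhaustively against independently coded oracles; the
  Cox engine is checked against a brute-force partial-likelihood grid.
- Ranking ties break lexicographically by country name for reproducibility.
- Fixed seeds drive only simulated inputs; all fits are deterministic given
  the data.

## Known limitations

- The midpoint placement of interval-known deaths slightly biases
  intensities when intervals are long; a proper integrated likelihood term
  would remove this.
- Standard errors assume a correctly specified Markov model; there is no
  robust/sandwich option.
- The frailty criteria and CF hospitalization threshold are configurable
  stand-ins for survey-specific operationalizations.
- Per-country Cox fits are unpooled; small countries with few deaths in a
  contrast group return NaN rather than a shrunken estimate.
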