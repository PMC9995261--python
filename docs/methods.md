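# Methods notes

These notes record the modelling conventions, the choices made where the
model description leaves the design open, and what the shipped parameter
fixture does and does not represent. Equations use monthly probabilities
`p`, hazard ratios `HR`, and a monthly cycle index `m = 1, 2, …`.

## Cohort structure and within-cycle ordering

The model is a deterministic Markov cohort over a factored state space. Two
subcohorts are fixed at entry (CKD-only, CKD+HF); within each, occupancy is
an array over CKD state × [NYHA class] × potassium category × RAASi status ×
treatment layer, plus one shared absorbing Dead state. The baseline joint
distribution is the product of the published marginals (stage, NYHA class
and potassium category independent at entry), since only marginals are
published.

Each cycle applies, in order:

1. **Potassium re-draw.** The potassium category is resampled from the
   phase/arm incidence triple (months 1, 2–3, ≥4; treated responders use the
   binder columns, everyone else the SoC columns), scaled per RAASi status
   by the HK-incidence hazard ratios, with the residual mass placed in
   normokalaemia. Hyperkalaemia is therefore a recurrent monthly event with
   no persistence beyond its cycle. Cycle 1 keeps the baseline categories
   (the month-1 incidence row, identical across arms, is used for event
   counting only).
2. **RAASi transitions** (from month 2; month 1 holds RAASi fixed while the
   response resolves). From max dose: down-titrate or discontinue; from
   sub-max: discontinue only (no return to max); from discontinued: return
   to max at 3.51%/month regardless of potassium. Months 2–3 use a single
   unstratified row; potassium stratification starts at month 4.
3. **Economics accrual** on the post-update occupancy (start-of-cycle
   convention: mass that dies this cycle still accrues this cycle).
4. **Clinical events and transitions.** MACE, hospitalisation and death
   probabilities are built per cell; survivors advance the CKD and NYHA
   chains independently.
5. **Treatment-status updates at cycle end** (next cycle effect): the
   month-1 responder split, the constant monthly stop, the forced stop at
   ESRD, and re-treatment. Because status changes take effect the following
   cycle, a patient's stopping month is still exposed and costed — this is
   what makes the no-retreatment mean exposure equal the geometric closed
   form `r·(1 + 1/d) + (1 − r)`, which the test suite checks to 1e-6.

The ordering (statuses resolved before event probabilities) follows the
model's influence structure: potassium and RAASi status must be current
before they can modify event risks. Where the description is silent the
ordering above is this package's declared convention.

## Probability conventions

* **Hazard ratios on the rate scale**: `p' = 1 − (1 − p)^HR`. This is the
  standard consistent mapping when ratios are estimated on rates rather
  than probabilities, and reduces to the identity at HR = 1.
* **Annual→monthly**: life-table `q` via `1 − (1 − q)^(1/12)`; annual event
  rates via `1 − exp(−rate/12)`.
* **Mortality floor**: monthly mortality is `max(modelled, life-table)`,
  with the life table blended across sexes by the cohort's proportion
  female and looked up at `floor(age)`; age advances +1/12 per cycle.
* **CKD+HF combination**: MACE, hospitalisation and death are estimated for
  the CKD state and the NYHA state separately and the **maximum** applies.
* **Age-dependent ESRD inputs**: a step function holding the value of the
  nearest knot ≤ age (knots 40/50/60/70, clamped outside); linear
  interpolation is available via `esrd.rule = "linear"`.
* **Discounting**: `(1 + r)^(−m/12)` indexed by cycle start, the same
  factor for costs and QALYs. Default 3.5%/year.
* **Half-cycle correction** is off by default (the description does not use
  one, and monthly cycles make it small — it shifts life expectancy by
  exactly half a cycle). The optional flag applies the telescoped trapezoid
  to occupancy-based streams only.
* **Horizon**: age 100 or alive mass < 1e-4, whichever first; residual mass
  contributes nothing (no terminal extrapolation).

## Treatment logic details

The public treatment status has two levels (on treatment / off), but the
engine refines "off" into a re-trigger-eligible layer (stopped via the
10.33%/month rate) and an ineligible layer (month-1 non-responders, and
anyone reaching ESRD on treatment). Only the eligible layer restarts when
the cycle's potassium category reaches 5.5–6 mmol/l or worse — re-treating
known non-responders would contradict the response concept (a config flag
restores the inclusive behaviour). Re-entry resumes responder event rates
without a second response split, incurs drug cost again, and is uncapped.
Non-responders and stopped patients incur SoC risks with no legacy effect.

The proportion still on RAASi at the end of month 1 is a per-arm config
field; the fixture uses a neutral 1.0 (no month-1 shortfall), consistent
with holding RAASi fixed during month 1, since no value is published.

## Probabilistic sensitivity analysis

Each uncertain scalar carries `(mean, se, family)`. Draws are
moment-matched: beta via `ν = m(1−m)/s² − 1`, `α = mν`, `β = (1−m)ν`
(probabilities, utilities, disutilities); gamma via `k = m²/s²`,
`θ = s²/m` (costs, hazard ratios); normal for demographics, truncated to
[0, 1] for proportions by rejection. `se = 0` means fixed, so structural
zeros stay exactly zero. After a draw, sampled starting marginals are
renormalised to sum to one, and incidence triples / from-max RAASi pairs
are rescaled only if a draw pushes their sum above one. Draw order follows
the schema's declaration order, making runs bit-reproducible by seed.
Standard errors printed in the source tables are used as printed; the
subsequent-month HK rows use the footnoted 10%-of-mean convention, which is
also applied to placeholder parameters and to the one published column
(binder RAASi discontinuation) printed without a standard error. The PSA
default is 1,000 draws (no published draw count); the one-way analysis
defaults to mean ± 1.96·SE ranges, so zero-SE parameters show zero span.

## The reference fixture: what it emulates, what it does not

The fixture is the complete, internally consistent parameter set the tests
and acceptance script run against. Main-text evidence is verbatim (with one
recorded exception: the published NYHA starting shares sum to 100.01% and
are stored renormalised). Background inputs live in the source's
supplementary appendices and are shipped as flagged placeholders chosen
once for UK plausibility: progression and event rates of the right order of
magnitude for an advanced-CKD cohort, NICE-style utilities decreasing with
severity, dialysis dominating state costs, and modifiers ordered by the
influence structure (less RAASi → worse renal/cardiac outcomes, less HK;
higher potassium → worse outcomes). The life table is a synthetic
sex-specific Gompertz calibrated to recent UK all-cause rates (q ≈ 1.25%/
0.83% male/female at 65), capped at 0.7, overridable by a real CSV table.

Consequences for interpretation: results computed from the fixture
reproduce the *structure* of the published findings — treatment adds cost
and (quality-adjusted) survival, reduces HK and RAASi-disruption events,
severe HK dominates the burden sweep, optimal RAASi management never loses
QALYs — but not the published totals, which depend on the appendix values.
Passing tests therefore demonstrate engine correctness and pattern
reproduction, not numeric agreement with the published cost-effectiveness
estimates; supplying the real appendix values via a config file is the
intended route to numeric comparison. Under the fixture, the mid-severity
sweep loss and the severe-HK cost increase fall short of the published
magnitudes, which is the expected signature of placeholder modifiers and
costs rather than an engine defect (the engine-level checks — closed forms,
matrix-power oracle, microsimulation agreement — are exact or within
Monte-Carlo error).

## Validation design

* **Closed forms**: hazard-ratio application, rate conversions, discount
  factors, the geometric exposure formula, beta/gamma moment matching.
* **Matrix-power oracle**: with modifiers at 1 and ESRD/death off, CKD
  occupancy equals the baseline chain's matrix powers exactly.
* **Microsimulation oracle**: an individual-level simulation consumes the
  identical per-cycle probability tables by Monte-Carlo sampling; cohort
  expectations must agree within 3 standard errors on life years, QALYs,
  total cost and every event count (100,000 individuals in the acceptance
  suite). The microsimulation does not clamp transiently negative
  per-individual cycle QALYs (the cohort clamp is a config-inconsistency
  guard that never triggers at the fixture), keeping it an unbiased
  estimator of the cohort expectation.
* **No-effect collapse**: copying SoC inputs over all binder-specific
  inputs makes the arms dynamically identical; differences collapse to
  floating-point accumulation (~1e-10 of the totals).

## Problem sizes

Default analyses: lifetime horizon of ~417 monthly cycles from age 65.3;
1,000 PSA draws; an 11-point rate grid per severity for the sweep; the
48-cell RAASi-value grid; 100,000 (acceptance) / 20,000 (unit-test)
individuals in the microsimulation. These sizes give Monte-Carlo error well
inside the assertion tolerances while keeping a full run in minutes.

## Known limitations

* No incident HF, no CKD-stage regression, no transplant failure, and no
  therapy-attributable adverse events — structural exclusions inherited
  from the model being implemented.
* HK events are memoryless month to month; there are no resolution
  dynamics, and the baseline categories influence only cycle 1.
* No up-titration pathway other than the discontinued→max return (no
  sub-max→max rates are published).
* Event disutilities are one-off per event (duration-weighting is not
  published); the joint CKD+HF utility is the minimum of the two state
  utilities rather than multiplicative.
* Cohort-level age and sex mix; between-patient heterogeneity beyond the
  factored states is only represented in the microsimulation's sampling
  noise.
* The microsimulation applies the neutral month-1 RAASi-persistence value;
  configs overriding that field are validated by the cohort engine only.
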