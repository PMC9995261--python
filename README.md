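# hkcea

A Markov cohort cost-effectiveness model of potassium-binder therapy
(patiromer) versus standard of care for hyperkalaemia (HK) management in
patients with advanced chronic kidney disease (CKD), with and without heart
failure (HF), from a UK healthcare-payer perspective.

The package is for health-economic modellers and methods researchers who
want a tested, config-driven, scriptable implementation of this model class:
factored disease chains, recurrent event dynamics, treatment-exposure logic,
probabilistic/deterministic sensitivity analysis, and an individual-level
simulation oracle for engine validation.

## The model

A cohort enters at age 65.3 split into CKD-only (58.02%) and CKD+HF (41.98%)
subcohorts and is propagated in monthly cycles over a lifetime horizon (to
age 100). The state space is the product of:

* a forward-only CKD chain: stages 3 → 4 → 5 → end-stage renal disease
  (separate dialysis and transplant states, with age-dependent transplant
  and ESRD-mortality inputs at knots 40/50/60/70);
* an NYHA I–IV chain for the CKD+HF subcohort (no incident HF);
* the current serum-potassium category (≤5, 5–5.5, 5.5–6, >6 mmol/l),
  re-drawn each cycle from phase- and arm-specific incidence tables;
* RAASi status (max dose, sub-max, discontinued; down-titration is
  irreversible, discontinuation reverses at 3.51%/month);
* binder treatment status (60.93% month-1 response, 10.33%/month
  discontinuation, forced stop at ESRD, re-treatment when potassium
  re-enters the 5.5–6 band or worse).

The chains progress independently but share a single death state. MACE,
hospitalisation and mortality are evaluated separately for the CKD and HF
chains and the **higher** of the two probabilities applies to the CKD+HF
subcohort; a sex-blended life table floors all mortality. Hazard-ratio
modifiers act on the rate scale, `p' = 1 − (1 − p)^HR`: less RAASi worsens
CKD progression, MACE, hospitalisation and death but lowers HK incidence;
higher potassium worsens MACE, hospitalisation and death.

Costs (GBP) accrue in eight ledger categories (treatment, HK events, CKD
management, RRT, MACE, hospitalisation, RAASi drug, RAASi titration), QALYs
as state utilities minus one-off event disutilities, both discounted at
3.5%/year. Arms are compared by the ICER ΔC/ΔQ and net monetary benefit
`NMB = λ·ΔQ − ΔC`.

### Parameter provenance

Every scalar carries a provenance flag. Published main-text inputs (starting
distributions, HK incidence, RAASi change rates, treatment parameters,
age-dependent ESRD inputs, HK event costs £0 / £223.11 / £2,933.49, the
discount rate) are encoded verbatim. Background inputs that the source keeps
in supplementary appendices are shipped as clearly flagged
`supplementary-placeholder` values — plausible for a UK setting, ordered to
respect the influence structure above, overridable from a YAML/JSON config
(`hkcea.load_parameters`), and **not** the published values. Headline totals
computed from the placeholder fixture therefore reproduce the published
*pattern* (signs, orderings, dominance class), not the published numbers.

| placeholder block | values (fixture) |
|---|---|
| CKD progression /month (max RAASi) | 3→4 0.9%, 4→5 1.2%, 5→dialysis 3.5% |
| NYHA worsening / improvement /month | 2.0/1.5/0.8% ; 0.5% each |
| MACE /month, by CKD3..transplant | 0.3/0.5/0.8/1.2/0.4% |
| MACE /month, by NYHA I–IV | 0.4/0.7/1.2/2.0% |
| hospitalisation /month, CKD ; NYHA | 1.5/2/3/5/2% ; 2/3/5/10% |
| death /month, CKD3–5 ; NYHA I–IV | 0.15/0.25/0.4% ; 0.2/0.4/0.9/2.5% |
| RAASi HRs (submax, discontinued) | progression 1.20/1.43 · MACE 1.15/1.35 · hosp. 1.10/1.25 · death 1.15/1.30 · HK 0.85/0.73 |
| potassium HRs (5–5.5, 5.5–6, >6) | MACE & hosp. 1.1/1.3/1.7 · death 1.2/1.6/3.0 |
| state costs /month | CKD3–5 £150/300/600 · dialysis £2,800 · transplant £300 · NYHA £50/100/200/400 |
| event costs | MACE £4,500 · hospitalisation £3,000 · RAASi titration £50 |
| drug costs /month | patiromer £172.50 · RAASi £1.50 (max) / £0.75 (submax) |
| utilities | CKD3–5 0.80/0.73/0.69 · dialysis 0.54 · transplant 0.71 · NYHA 0.815/0.72/0.59/0.51 (joint = min) |
| event disutilities | HK 0/0.002/0.010 · MACE 0.06 · hospitalisation 0.02 |
| life table | synthetic UK-like Gompertz by sex (see `make_life_table`) |

## Worked example

```python
from hkcea import make_reference_fixture, run_base_case

res = run_base_case(make_reference_fixture())
print(res.to_table().round(3).to_string(index=False))
```

prints (abridged):

```
   results          quantity  patiromer        soc  incremental
Discounted Total costs (GBP) 109957.256 109615.650      341.606
Discounted         treatment   1217.712      0.000     1217.712
Discounted                HK    320.542    498.858     -178.316
Discounted               RRT  66397.948  67397.729     -999.781
Discounted  Total life years      8.633      8.537        0.096
Discounted       Total QALYs      5.759      5.682        0.077
Discounted   ICER (GBP/QALY)        NaN        NaN     4450.214
```

Reading it: under the placeholder fixture the treated arm gains 0.096
discounted life years and 0.077 QALYs at £342 extra — drug spend (+£1,218)
partly offset by avoided HK events and delayed renal replacement therapy —
giving an ICER of about £4,450 per QALY. Patients average 7.3 months on the
binder, with roughly 201 fewer moderate (K 5.5–6) HK events, 220 fewer RAASi
discontinuations and 118 fewer down-titrations per 1,000 patients versus
standard of care.

The `examples/` directory has one short script per capability: base case,
PSA/CEAC, the HK-burden sweep, the RAASi-value grid and the
cohort-vs-microsimulation check. A thin CLI covers the same ground:

```bash
hkcea validate                 # check a config (or the fixture)
hkcea run --out out/           # base case bundle (CSV + JSON + manifest)
hkcea psa --n 1000 --seed 7 --out out/
hkcea owsa | hkcea sweep-hk | hkcea raasi-value
hkcea fixture --out config.yaml   # write the fixture as a starting config
```

## Layout

```
src/hkcea/
  parameters.py   # schema, validation, moment-matched PSA sampling, I/O
  reference.py    # reference fixture + synthetic life table
  states.py       # factored state space, initial cohort
  progression.py  # CKD/NYHA chains, ESRD, events, mortality, modifiers
  potassium.py    # HK incidence phases, RAASi transition tables
  treatment.py    # response split, stopping, re-treatment
  engine.py       # cohort propagation + microsimulation oracle
  economics.py    # discounting, cost ledger, QALYs, ICER/NMB
  analyses.py     # base case, PSA, OWSA, HK sweep, RAASi-value grid
  cli.py          # thin typer CLI
  data/parameter_set.schema.json
docs/methods.md   # modelling notes: conventions, assumptions, limitations
```
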