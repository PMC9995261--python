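"""Lifetime base-case cost-effectiveness of the potassium binder vs SoC.

Runs both arms of the Markov cohort model on the reference parameter set and
prints the results table: discounted/undiscounted costs by category, life
years, QALYs and the incremental cost-effectiveness ratio (GBP per QALY
gained; below ~20,000-30,000 GBP/QALY is conventionally cost-effective in
the UK)."""

from hkcea import make_reference_fixture, run_base_case

p = make_reference_fixture()
res = run_base_case(p)

print(res.to_table().round(3).to_string(index=False))
print()
print(f"Incremental cost  : {res.delta_cost:10.0f} GBP")
print(f"Incremental QALYs : {res.delta_qaly:10.3f}")
print(f"ICER              : {res.icer:10.0f} GBP/QALY ({res.dominance})")
print()
print("The treated arm lives longer at extra cost; the ICER is the price "
      "paid per quality-adjusted life year gained.")
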