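"""Probabilistic sensitivity analysis and the acceptability curve.

Draws parameter sets from their uncertainty distributions (beta for
probabilities and utilities, gamma for costs and hazard ratios, normal for
demographics), reruns the model per draw, and prints the probability that
treatment is cost-effective across willingness-to-pay thresholds."""

from hkcea import make_reference_fixture, run_psa

p = make_reference_fixture()
res = run_psa(p, n_draws=200, seed=7)   # use ~1000 draws for smooth curves

print(f"{res.n_draws} draws ({res.n_skipped} skipped)")
print(res.ceac_frame().round(3).to_string(index=False))
print()
print(f"P(cost-effective at 20,000 GBP/QALY) = {res.ceac(20000.0)[0]:.1%}")
print(f"P(cost-effective at 30,000 GBP/QALY) = {res.ceac(30000.0)[0]:.1%}")
print()
print("Each row is the share of parameter draws in which the net monetary "
      "benefit (WTP x dQALY - dCost) is positive.")
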