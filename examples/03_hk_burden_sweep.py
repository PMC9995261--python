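"""Lifetime burden of hyperkalaemia by severity.

Varies the annual hyperkalaemia rate of one severity band at a time
(0-0.5/year, standard-of-care management, no binder) and prints the lifetime
cost/QALY/life-year change versus an otherwise identical cohort with no
hyperkalaemia."""

from hkcea import make_reference_fixture, run_hk_sweep

p = make_reference_fixture()
sweep = run_hk_sweep(p, rates=[0.0, 0.1, 0.25, 0.5])

print(sweep.table.round(4).to_string(index=False))
print()
for cat, label in (("k_5_55", "K 5-5.5"), ("k_55_6", "K 5.5-6"),
                   ("k_gt6", "K >6")):
    print(f"{label:8s}: QALY loss at 0.5/yr = "
          f"{sweep.loss(cat, 0.5, 'qaly'):.3f}, "
          f"cost change = {-sweep.loss(cat, 0.5, 'cost'):+.0f} GBP")
print()
print("Severe events (K>6 mmol/l) carry the largest QALY losses and, through "
      "their 2,933 GBP management cost, raise lifetime costs; milder events "
      "mostly shorten life, which can lower lifetime spending.")
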