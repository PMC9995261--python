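"""Validating the cohort engine against an individual-level simulation.

Runs 20,000 simulated patients through the same per-cycle probabilities the
cohort engine uses and compares the Monte-Carlo means with the cohort
expectations (they should agree within a few standard errors)."""

import numpy as np

from hkcea import make_reference_fixture, run_cohort, run_microsimulation

p = make_reference_fixture()
n = 20_000
cohort = run_cohort("patiromer", p)
micro = run_microsimulation("patiromer", p, n, seed=11)

print(f"{'quantity':28s}{'cohort':>10s}{'microsim':>10s}{'z-score':>9s}")
for key, value in (("ly", cohort.total_ly()),
                   ("qaly", cohort.total_qaly()),
                   ("cost", cohort.total_cost()),
                   ("hk_55_6", cohort.total_events("hk_55_6")),
                   ("raasi_discontinuation",
                    cohort.total_events("raasi_discontinuation"))):
    arr = micro.individual[key]
    se = arr.std(ddof=1) / np.sqrt(n)
    z = (arr.mean() - value) / se
    print(f"{key:28s}{value:10.3f}{arr.mean():10.3f}{z:9.2f}")
print()
print("|z| values of order 1 indicate the deterministic cohort expectations "
      "match the sampled individual-level dynamics.")
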