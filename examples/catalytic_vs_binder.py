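"""Compare a stoichiometric binder with a catalytic target inactivator
across doses, against an abundant cytosolic target (1e5 copies/cell).

A binder must occupy its target one-to-one, so once the cytosolic
target outnumbers what delivery can supply, inhibition collapses.  A
catalytic cargo (here k_cat = 2.35/min, the rate of a RAS-cleaving
enzyme) turns over and is released intact, so even trace delivery
produces deep, long-lasting inhibition.
"""

import dataclasses

from cytodel import Mode, SolverOptions, load_preset, make_regimen, simulate
from cytodel.outcomes import inhibitory_effect

opts = SolverOptions(n_shells=64)
catalytic_scenario = load_preset("tumor_catalytic")
binder_agent = dataclasses.replace(catalytic_scenario.agent,
                                   mode=Mode.BINDER, k_cat_per_min=0.0)

print("single dose, 1e5 target copies/cell, 168 h horizon")
print(f"{'plasma peak':>12} | {'binder effect':>14} | {'catalytic effect':>16}")
for peak_m in (2e-8, 2e-7, 1e-6):
    regimen = make_regimen("single", peak_m=peak_m, half_life_h=2.55)
    ie = {}
    for label, agent in (("binder", binder_agent),
                         ("catalytic", catalytic_scenario.agent)):
        sc = catalytic_scenario.replace(agent=agent, regimen=regimen)
        ie[label] = inhibitory_effect(simulate(sc, t_end_h=168.0, options=opts))
    print(f"{1e9 * peak_m:9.0f} nM | {ie['binder']:11.2f} f-h | "
          f"{ie['catalytic']:13.2f} f-h")

print("\nEffect is the volume-averaged inhibition integrated over time "
      "(fraction-hours).\nThe catalytic cargo dominates at every dose, "
      "most dramatically at low ones.")
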