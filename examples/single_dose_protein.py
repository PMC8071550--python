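"""Simulate a single 1 uM dose of a 70 kDa EpCAM-targeted protein in a
no-convection tumor and report the delivery and inhibition metrics.

The printed numbers are: when the free cytosolic target is most depleted
(time of maximum delivery), how strong the volume-averaged knockdown
gets (maximum inhibition), its time integral (inhibitory effect), and
how far from the capillary half of the delivered agent sits — the
footprint of the binding-site barrier.
"""

from cytodel import SolverOptions, load_preset, simulate
from cytodel.outcomes import report

scenario = load_preset("tumor_protein_noconv")
trajectory = simulate(scenario, t_end_h=72.0,
                      options=SolverOptions(n_shells=100))
metrics = report(trajectory)

print("70 kDa protein, Kd 68 pM, single dose to 1 uM plasma, 72 h")
print(f"  time of maximum delivery : {metrics.t_max_delivery_h:6.2f} h")
print(f"  maximum inhibition       : {100 * metrics.max_inhibition:6.1f} %")
print(f"  inhibitory effect        : {metrics.inhibitory_effect_h:6.2f} fraction-hours")
print(f"  depth holding 50% agent  : {metrics.penetration_depth_50_um:6.1f} um")

# radial snapshot at the time of maximum delivery
import numpy as np

i = int(np.argmin(np.abs(trajectory.times_h - metrics.t_max_delivery_h)))
total = trajectory.agent_tissue_concentration()[i]
print("\nradius (um)   total agent (nM, tissue basis)")
for j in range(0, trajectory.grid.n_shells, 20):
    print(f"  {trajectory.grid.centers_um[j]:7.1f}     {1e9 * total[j]:10.3f}")
print("\nMost of the agent is confined to the first cell layers around "
      "the capillary: the binding-site barrier.")
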