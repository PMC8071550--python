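"""Reaction network for the six delivery species (plus cold competitor).

Species and bases
-----------------
Per liter of whole tissue:

* ``A_int``   free agent in the interstitium
* ``R_free``  unbound cell-surface receptor
* ``RC_surf`` receptor-agent surface complex

Per liter of cytosol:

* ``A_cyt``   free agent delivered to the cytosol
* ``T_free``  free (functional) cytosolic target
* ``TC_cyt``  inhibitory agent-target complex

A cold competitor adds ``A_int_cold`` and ``RC_surf_cold``; it has no
cytosolic species.

Processes: reversible surface binding (the ligand concentration sensed
by receptors is the interstitial free concentration ``A_int/eps``),
internalization of the surface complex at ``ke`` with an endosomal
escape fraction reaching the cytosol and the remainder degraded,
receptor recycling/synthesis balancing internalization (steady-state
receptor pool), first-order cytosolic decay of the free agent, target
synthesis/turnover, reversible target engagement, and — in catalytic
mode — turnover of the complex at ``k_cat`` releasing the agent intact
while the inactivated target leaves the system.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .grid import RadialGrid
from .params import AgentSpec, Mode, Rates, TargetSpec, TissueSpec, derive_rates

SPECIES = ("A_int", "R_free", "RC_surf", "A_cyt", "T_free", "TC_cyt")
COLD_SPECIES = ("A_int_cold", "RC_surf_cold")


def reaction_rates(
    fields: Mapping[str, np.ndarray],
    rates: Rates,
    catalytic: bool,
    receptor_steady_state: bool = True,
    cold_rates: Rates | None = None,
) -> dict[str, np.ndarray]:
    """d/dt contributions of the reaction network (transport excluded).

    ``fields`` maps species names to per-shell concentration arrays;
    the returned dict has the same keys and shapes.  Pure function of
    the current state.
    """
    A = fields["A_int"]
    R = fields["R_free"]
    C = fields["RC_surf"]
    B = fields["A_cyt"]
    T = fields["T_free"]
    X = fields["TC_cyt"]

    bind = rates.kon_r * (A / rates.eps) * R - rates.koff_r * C
    internalize = rates.ke * C
    recycle = internalize if receptor_steady_state else 0.0

    out: dict[str, np.ndarray] = {}
    out["A_int"] = -bind
    out["R_free"] = -bind + recycle
    out["RC_surf"] = bind - internalize

    if rates.phi > 0:
        escape_flux = rates.escape * internalize / rates.phi  # cytosol basis
    else:
        escape_flux = 0.0
    bind_t = rates.kon_t * B * T - rates.koff_t * X
    turnover = rates.kcat * X if catalytic else 0.0
    # the agent-target complex is degraded at the agent's cytosolic decay
    # rate (the bound agent remains proteasome-accessible and the complexed
    # target is destroyed with it), so holding the target down requires a
    # sustained delivery rate, not just accumulated mass
    out["A_cyt"] = escape_flux - rates.kdec_cyt * B - bind_t + turnover
    out["T_free"] = rates.ksyn - rates.kdec_target * T - bind_t
    out["TC_cyt"] = bind_t - turnover - rates.kdec_cyt * X

    if cold_rates is not None and "A_int_cold" in fields:
        A2 = fields["A_int_cold"]
        C2 = fields["RC_surf_cold"]
        bind2 = cold_rates.kon_r * (A2 / cold_rates.eps) * R - cold_rates.koff_r * C2
        internalize2 = cold_rates.ke * C2
        out["A_int_cold"] = -bind2
        out["RC_surf_cold"] = bind2 - internalize2
        out["R_free"] = out["R_free"] - bind2 + (internalize2 if receptor_steady_state else 0.0)

    return out


def reaction_terms(
    fields: Mapping[str, np.ndarray],
    agent: AgentSpec,
    tissue: TissueSpec,
    target: TargetSpec,
    cold_agent: AgentSpec | None = None,
) -> dict[str, np.ndarray]:
    """Reaction d/dt terms for given specs; see :func:`reaction_rates`."""
    rates = derive_rates(agent, tissue, target)
    cold_rates = (derive_rates(cold_agent, tissue, target)
                  if cold_agent is not None else None)
    return reaction_rates(fields, rates, catalytic=agent.mode is Mode.CATALYTIC,
                          receptor_steady_state=tissue.receptor_steady_state,
                          cold_rates=cold_rates)


def initial_state(
    tissue: TissueSpec,
    target: TargetSpec,
    grid: RadialGrid,
    with_cold: bool = False,
) -> dict[str, np.ndarray]:
    """Pre-dose equilibrium: empty interstitium and cytosol, full free
    receptor pool, target at its synthesis/turnover steady state."""
    n = grid.n_shells
    zeros = lambda: np.zeros(n)
    state = {name: zeros() for name in SPECIES}
    state["R_free"] = np.full(n, tissue.receptor_concentration_m)
    state["T_free"] = np.full(n, target.baseline_concentration_m)
    if with_cold:
        for name in COLD_SPECIES:
            state[name] = zeros()
    return state
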