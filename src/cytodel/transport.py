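"""Finite-volume radial transport in the Krogh annulus.

Diffusion uses central differences on shell centers; convection uses
first-order upwinding, which keeps the scheme positivity-preserving at
the modest Peclet numbers of interstitial flow.  The capillary wall is
a flux boundary driven by the plasma concentration; the outer (Krogh)
boundary is closed to diffusion and, when convection is on, drains
convectively into the lymphatics.
"""

from __future__ import annotations

import numpy as np

from .grid import RadialGrid

CM_PER_UM = 1e-4


def wall_flux(
    c_plasma_m: float,
    c_int_surface_m: float,
    permeability_cm_s: float,
    void_fraction: float,
    v_wall_cm_s: float = 0.0,
    reflection_coefficient: float = 1.0,
) -> float:
    """Trans-capillary solute flux density, M*cm/s per unit wall area.

    Diffusive exchange P*(C_p - C_i/eps) plus, when transmural
    filtration drives interstitial convection, solvent drag
    (1 - sigma)*v_wall*C_p of plasma solute carried along with the
    filtrate (Patlak flux; sigma is the osmotic reflection coefficient
    of the agent at the vessel wall).  ``c_int_surface_m`` is the
    tissue-basis concentration in the shell abutting the wall; dividing
    by the void fraction gives the free interstitial concentration that
    equilibrates against plasma.
    """
    diffusive = permeability_cm_s * (c_plasma_m - c_int_surface_m / void_fraction)
    drag = (1.0 - reflection_coefficient) * v_wall_cm_s * c_plasma_m
    return diffusive + drag


def transport_operator(
    field: np.ndarray,
    grid: RadialGrid,
    diffusivity_cm2_s: float,
    v_wall_um_s: float = 0.0,
    wall_flux_density: float = 0.0,
    outer_sink: bool = True,
) -> np.ndarray:
    """Per-shell d/dt of a mobile interstitial species (tissue basis).

    Radial velocity decays as v(r) = v_wall * r_cap / r (incompressible
    radial outflow from the capillary).  ``wall_flux_density`` is the
    solute flux density crossing the capillary wall into the innermost
    shell (positive inward), as returned by :func:`wall_flux`.
    """
    edges_cm = grid.edges_um * CM_PER_UM
    areas_cm2 = grid.shell_areas_um2 * CM_PER_UM**2
    dr_cm = np.diff(edges_cm)
    n = grid.n_shells

    # edge fluxes, positive outward; length n+1
    flux = np.zeros(n + 1)
    circ = 2.0 * np.pi * edges_cm  # edge circumference per unit length

    # interior edges
    dr_c = 0.5 * (dr_cm[:-1] + dr_cm[1:])  # center-to-center distances
    diff_flux = -diffusivity_cm2_s * np.diff(field) / dr_c
    flux[1:n] = circ[1:n] * diff_flux
    if v_wall_um_s > 0.0:
        v_edge = v_wall_um_s * CM_PER_UM * edges_cm[0] / edges_cm[1:n]
        flux[1:n] += circ[1:n] * v_edge * field[:-1]  # upwind (outward flow)
        if outer_sink:
            v_out = v_wall_um_s * CM_PER_UM * edges_cm[0] / edges_cm[n]
            flux[n] = circ[n] * v_out * field[-1]
    # outward-positive flux at the inner edge: the wall influx enters shell 0
    flux[0] = circ[0] * wall_flux_density

    return -np.diff(flux) / areas_cm2
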