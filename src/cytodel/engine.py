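"""Method-of-lines integration of the full delivery model.

The six (or eight, with a cold competitor) species on the radial grid
are stacked into one state vector and advanced with a stiff implicit
solver (BDF) using a sparse Jacobian pattern.  Dose times are
integration restart points because the plasma forcing is discontinuous
there.  Three auxiliary cumulative states (wall influx, degradation,
convective outflow of the warm agent) are integrated alongside the
species so that a global mass audit is available for every output time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import coo_matrix

from .dosing import DoseSpecies, plasma_concentration
from .grid import RadialGrid, build_grid
from .kinetics import COLD_SPECIES, SPECIES, initial_state, reaction_rates
from .params import Mode, Scenario, canonical_dict, derive_rates
from .transport import CM_PER_UM, transport_operator, wall_flux

AUX = ("influx", "degraded", "outflow")


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings for :func:`simulate`."""

    n_shells: int = 100
    output_step_h: float = 0.25
    rtol: float = 1e-8
    atol: float = 1e-12
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.n_shells < 4:
            raise ValueError("n_shells must be at least 4")
        if self.output_step_h <= 0:
            raise ValueError("output_step_h must be positive")


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails or produces unphysical
    (significantly negative) concentrations."""


@dataclass(frozen=True)
class Trajectory:
    """Simulation output: radial fields of every species over time.

    ``fields[name]`` has shape (n_times, n_shells).  ``audit`` carries
    the cumulative warm-agent wall influx, degradation and convective
    outflow (arbitrary but mutually consistent units, mol per unit
    capillary length) used by :meth:`mass_balance_residual`.
    """

    times_h: np.ndarray
    fields: Mapping[str, np.ndarray]
    grid: RadialGrid
    scenario: Scenario
    options: SolverOptions
    audit: Mapping[str, np.ndarray]
    provenance: str

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.fields)

    def average(self, name: str) -> np.ndarray:
        """Tissue-volume-averaged time series of one species."""
        return self.grid.average(self.fields[name])

    def agent_tissue_concentration(self) -> np.ndarray:
        """Total warm agent per liter of tissue, all compartments,
        shape (n_times, n_shells)."""
        rates = derive_rates(self.scenario.agent, self.scenario.tissue,
                             self.scenario.target)
        return (self.fields["A_int"] + self.fields["RC_surf"]
                + rates.phi * (self.fields["A_cyt"] + self.fields["TC_cyt"]))

    def agent_mass_per_length(self) -> np.ndarray:
        """Warm agent in the whole annulus per unit capillary length."""
        areas = self.grid.shell_areas_um2 * CM_PER_UM**2
        return self.agent_tissue_concentration() @ areas

    def mass_balance_residual(self) -> np.ndarray:
        """(influx - degraded - outflow - in_tissue) / max(influx),
        per output time; near zero for a conservative integration."""
        influx = self.audit["influx"]
        scale = max(float(influx[-1]), 1e-300)
        resid = influx - self.audit["degraded"] - self.audit["outflow"] \
            - self.agent_mass_per_length()
        return resid / scale

    def to_frame(self):
        """Tidy table with columns time_h, radius_um, species,
        concentration_M."""
        import pandas as pd

        nt, n = len(self.times_h), self.grid.n_shells
        frames = []
        for name, arr in self.fields.items():
            frames.append(pd.DataFrame({
                "time_h": np.repeat(self.times_h, n),
                "radius_um": np.tile(self.grid.centers_um, nt),
                "species": name,
                "concentration_M": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


def _jacobian_sparsity(n: int, with_cold: bool) -> coo_matrix:
    """Structural Jacobian of the stacked system.

    Within a shell all species couple; the interstitial species also
    couple to their radial neighbors; the three auxiliary rows depend on
    species but nothing depends on them.
    """
    names = SPECIES + (COLD_SPECIES if with_cold else ())
    ns = len(names)
    idx = {name: i for i, name in enumerate(names)}
    size = ns * n + len(AUX)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    shells = np.arange(n)

    def couple(a: str, b: str) -> None:
        rows.append(idx[a] * n + shells)
        cols.append(idx[b] * n + shells)

    surface = ["A_int", "R_free", "RC_surf"]
    if with_cold:
        surface += ["A_int_cold", "RC_surf_cold"]
    for a in surface:
        for b in surface:
            couple(a, b)
    for a in ("A_cyt", "T_free", "TC_cyt"):
        for b in ("RC_surf", "A_cyt", "T_free", "TC_cyt"):
            couple(a, b)
    # radial neighbors for mobile species
    mobile = ["A_int"] + (["A_int_cold"] if with_cold else [])
    for name in mobile:
        base = idx[name] * n
        rows.append(base + shells[:-1]); cols.append(base + shells[1:])
        rows.append(base + shells[1:]); cols.append(base + shells[:-1])
    # aux rows
    aux0 = ns * n
    rows.append(np.array([aux0 + 0])); cols.append(np.array([idx["A_int"] * n]))
    rows.append(np.full(n, aux0 + 1)); cols.append(idx["RC_surf"] * n + shells)
    rows.append(np.full(n, aux0 + 1)); cols.append(idx["A_cyt"] * n + shells)
    rows.append(np.array([aux0 + 2])); cols.append(np.array([idx["A_int"] * n + n - 1]))

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    return coo_matrix((np.ones_like(r, dtype=float), (r, c)), shape=(size, size))


def _provenance_hash(scenario: Scenario, options: SolverOptions,
                     t_end_h: float) -> str:
    payload = {"scenario": canonical_dict(scenario),
               "options": canonical_dict(options), "t_end_h": t_end_h}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def simulate(
    scenario: Scenario,
    t_end_h: float = 168.0,
    options: SolverOptions | None = None,
    grid: RadialGrid | None = None,
) -> Trajectory:
    """Integrate the coupled delivery model over ``[0, t_end_h]`` hours.

    Raises :class:`IntegrationError` on solver failure or if any species
    drops below the negativity tolerance implied by the solver settings.
    """
    if t_end_h <= 0:
        raise ValueError("t_end_h must be positive")
    opts = options or SolverOptions()
    tissue, target = scenario.tissue, scenario.target
    agent = scenario.agent
    regimen = scenario.regimen
    if regimen is None:
        raise ValueError("scenario requires a dose regimen")
    cold = scenario.cold_agent
    has_cold_events = any(e.species is DoseSpecies.COLD for e in regimen.events)
    with_cold = cold is not None and has_cold_events

    if grid is None:
        grid = build_grid(tissue, opts.n_shells)
    n = grid.n_shells
    names = list(SPECIES) + (list(COLD_SPECIES) if with_cold else [])
    ns = len(names)

    rates = derive_rates(agent, tissue, target)
    cold_rates = derive_rates(cold, tissue, target) if with_cold else None
    catalytic = agent.mode is Mode.CATALYTIC
    steady = tissue.receptor_steady_state
    v_wall = tissue.fluid_velocity_at_wall_um_s
    sink = tissue.outer_boundary_sink
    areas_cm2 = grid.shell_areas_um2 * CM_PER_UM**2
    circ0 = 2.0 * np.pi * grid.edges_um[0] * CM_PER_UM
    circ_out = 2.0 * np.pi * grid.edges_um[-1] * CM_PER_UM
    v_out = (v_wall * CM_PER_UM * grid.edges_um[0] / grid.edges_um[-1]
             if (v_wall > 0 and sink) else 0.0)

    def rhs(t_s: float, y: np.ndarray) -> np.ndarray:
        t_h = t_s / 3600.0
        fields = {name: y[i * n:(i + 1) * n] for i, name in enumerate(names)}
        dy = reaction_rates(fields, rates, catalytic, steady, cold_rates)

        cp = plasma_concentration(regimen, DoseSpecies.WARM, t_h)
        jw = wall_flux(cp, fields["A_int"][0], rates.permeability_cm_s,
                       rates.eps, v_wall * CM_PER_UM,
                       tissue.reflection_coefficient)
        dy["A_int"] = dy["A_int"] + transport_operator(
            fields["A_int"], grid, rates.diffusivity_cm2_s, v_wall, jw, sink)

        if with_cold:
            cp2 = plasma_concentration(regimen, DoseSpecies.COLD, t_h)
            jw2 = wall_flux(cp2, fields["A_int_cold"][0],
                            cold_rates.permeability_cm_s, cold_rates.eps,
                            v_wall * CM_PER_UM, tissue.reflection_coefficient)
            dy["A_int_cold"] = dy["A_int_cold"] + transport_operator(
                fields["A_int_cold"], grid, cold_rates.diffusivity_cm2_s,
                v_wall, jw2, sink)

        out = np.empty_like(y)
        for i, name in enumerate(names):
            out[i * n:(i + 1) * n] = dy[name]
        # cumulative warm-agent audit, mol per unit capillary length
        out[ns * n + 0] = circ0 * jw
        out[ns * n + 1] = np.dot(areas_cm2,
                                 (1.0 - rates.escape) * rates.ke * fields["RC_surf"]
                                 + rates.phi * rates.kdec_cyt
                                 * (fields["A_cyt"] + fields["TC_cyt"]))
        out[ns * n + 2] = circ_out * v_out * fields["A_int"][-1]
        return out

    y0 = np.zeros(ns * n + len(AUX))
    init = initial_state(tissue, target, grid, with_cold=with_cold)
    for i, name in enumerate(names):
        y0[i * n:(i + 1) * n] = init[name]

    sparsity = _jacobian_sparsity(n, with_cold)
    out_times_h = np.arange(0.0, t_end_h + 1e-9, opts.output_step_h)
    event_times = [t for t in regimen.event_times() if 0.0 < t < t_end_h]
    boundaries = np.unique(np.concatenate([[0.0, t_end_h], event_times]))

    times_acc: list[np.ndarray] = []
    ys_acc: list[np.ndarray] = []
    y = y0
    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        inside = out_times_h[(out_times_h > seg_start) & (out_times_h < seg_end)]
        t_eval = np.unique(np.concatenate([[seg_start], inside, [seg_end]]))
        sol = solve_ivp(
            rhs, (seg_start * 3600.0, seg_end * 3600.0), y,
            method=opts.method, t_eval=t_eval * 3600.0,
            rtol=opts.rtol, atol=opts.atol, jac_sparsity=sparsity)
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in [{seg_start}, {seg_end}] h: {sol.message}")
        times_acc.append(sol.t / 3600.0)
        ys_acc.append(sol.y)
        y = sol.y[:, -1]

    # stitch segments, dropping duplicated boundary points
    times = times_acc[0]
    ys = ys_acc[0]
    for t_seg, y_seg in zip(times_acc[1:], ys_acc[1:]):
        times = np.concatenate([times, t_seg[1:]])
        ys = np.concatenate([ys, y_seg[:, 1:]], axis=1)

    fields = {name: ys[i * n:(i + 1) * n, :].T for i, name in enumerate(names)}
    audit = {name: ys[ns * n + i, :] for i, name in enumerate(AUX)}

    neg_tol = max(1e3 * opts.atol, 1e-12)
    worst = min(float(arr.min()) for arr in fields.values())
    if worst < -neg_tol:
        raise IntegrationError(
            f"negative concentration {worst:.3e} beyond tolerance {neg_tol:.1e}")

    return Trajectory(
        times_h=times, fields=fields, grid=grid, scenario=scenario,
        options=opts, audit=audit,
        provenance=_provenance_hash(scenario, opts, t_end_h))
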