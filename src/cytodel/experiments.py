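"""In silico experiment drivers: parameter sweeps, affinity optimization,
affinity x receptor-density heatmaps and side-by-side strategy comparisons.

All drivers are deterministic; repeated runs with identical inputs give
identical tables.  Simulations are memoized on a hash of the full
parameter set so that overlapping sweeps do not recompute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import outcomes
from .engine import IntegrationError, SolverOptions, Trajectory, simulate
from .params import Mode, Scenario, canonical_dict

log = logging.getLogger(__name__)

METRICS: dict[str, Callable[[Trajectory], float]] = {
    "max_inhibition": outcomes.max_inhibition,
    "inhibitory_effect": outcomes.inhibitory_effect,
    "time_of_max_delivery": outcomes.time_of_max_delivery,
    "min_avg_free_target": lambda tr: float(
        np.min(tr.grid.average(tr.fields["T_free"]))),
}

#: Inverted golden ratio for the line search on log10 Kd.
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _set_by_path(scenario: Scenario, path: str, value) -> Scenario:
    """Return a scenario with the dotted attribute ``path`` replaced,
    e.g. ``agent.kd_receptor_m`` or ``tissue.receptors_per_cell``."""
    head, _, rest = path.partition(".")
    if not rest:
        return scenario.replace(**{head: value})
    obj = getattr(scenario, head)
    parent, _, leaf = rest.rpartition(".")
    if parent:
        raise ValueError(f"parameter path {path!r} nests too deeply")
    return scenario.replace(**{head: dataclasses.replace(obj, **{leaf: value})})


class SimulationCache:
    """Memoizes trajectories by a hash of scenario + solver settings."""

    def __init__(self, enabled: bool = True) -> None:
        self.enabled = enabled
        self._store: dict[str, Trajectory] = {}
        self.hits = 0
        self.misses = 0

    def key(self, scenario: Scenario, t_end_h: float, opts: SolverOptions) -> str:
        payload = {"scenario": canonical_dict(scenario),
                   "t_end_h": t_end_h, "opts": canonical_dict(opts)}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()

    def run(self, scenario: Scenario, t_end_h: float, opts: SolverOptions) -> Trajectory:
        if not self.enabled:
            return simulate(scenario, t_end_h=t_end_h, options=opts)
        k = self.key(scenario, t_end_h, opts)
        if k not in self._store:
            self.misses += 1
            self._store[k] = simulate(scenario, t_end_h=t_end_h, options=opts)
        else:
            self.hits += 1
        return self._store[k]


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional parameter sweep of a fixed scenario.

    ``parameter`` is a dotted path into the scenario (e.g.
    ``agent.kd_receptor_m``); ``values`` the grid (log-spaced for
    affinities); ``metric`` one of ``max_inhibition``,
    ``inhibitory_effect``, ``time_of_max_delivery`` or
    ``min_avg_free_target``.
    """

    scenario: Scenario
    parameter: str
    values: tuple[float, ...]
    metric: str = "max_inhibition"
    t_end_h: float = 72.0
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("sweep needs at least one value")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


def run_sweep(spec: SweepSpec, cache: SimulationCache | None = None) -> pd.DataFrame:
    """Run one simulation per grid value; failed runs are recorded with a
    NaN metric and the sweep continues."""
    cache = cache or SimulationCache()
    fn = METRICS[spec.metric]
    rows = []
    for value in spec.values:
        try:
            sc = _set_by_path(spec.scenario, spec.parameter, value)
            traj = cache.run(sc, spec.t_end_h, spec.options)
            metric = fn(traj)
            err = ""
        except (IntegrationError, ValueError) as exc:
            log.warning("sweep point %s=%g failed: %s", spec.parameter, value, exc)
            metric, err = math.nan, str(exc)
        rows.append({"value": value, "metric": metric, "error": err})
    df = pd.DataFrame(rows)
    df.attrs["parameter"] = spec.parameter
    df.attrs["metric"] = spec.metric
    return df


@dataclass(frozen=True)
class OptimumResult:
    kd_m: float
    objective: float
    on_bound: bool
    degenerate: bool
    n_simulations: int


def optimal_affinity(
    scenario: Scenario,
    kd_bounds_m: tuple[float, float] = (1e-12, 1e-5),
    objective: str = "min_avg_free_target",
    n_coarse: int = 13,
    log_tol: float = 0.02,
    t_end_h: float = 72.0,
    options: SolverOptions | None = None,
    cache: SimulationCache | None = None,
) -> OptimumResult:
    """Receptor affinity giving the best tissue outcome.

    Coarse log-spaced Kd scan followed by golden-section refinement on
    log10 Kd.  The default objective is maximal delivery — the minimum
    over time of the volume-averaged free target, to be minimized; the
    alternatives ``max_inhibition`` and ``inhibitory_effect`` are
    maximized.  Returns the optimum with flags for a bound-touching or
    degenerate (flat) objective.
    """
    lo, hi = kd_bounds_m
    if not (0 < lo < hi):
        raise ValueError("invalid Kd bounds")
    if math.log10(hi / lo) < 4:
        raise ValueError("Kd bounds should span at least 4 orders of magnitude")
    opts = options or SolverOptions()
    cache = cache or SimulationCache()
    fn = METRICS[objective]
    sign = 1.0 if objective == "min_avg_free_target" else -1.0

    n_sim = 0

    def evaluate(log_kd: float) -> float:
        nonlocal n_sim
        sc = _set_by_path(scenario, "agent.kd_receptor_m", 10.0**log_kd)
        n_sim += 1
        return sign * fn(cache.run(sc, t_end_h, opts))

    grid = np.linspace(math.log10(lo), math.log10(hi), n_coarse)
    coarse = np.array([evaluate(g) for g in grid])
    spread = coarse.max() - coarse.min()
    degenerate = not np.isfinite(spread) or spread <= 1e-12 * max(
        1.0, abs(float(coarse.min())))
    i = int(np.argmin(coarse))
    if degenerate:
        return OptimumResult(10.0**grid[i], float(coarse[i]), False, True, n_sim)
    if i in (0, n_coarse - 1):
        return OptimumResult(10.0**grid[i], float(sign * coarse[i]), True, False, n_sim)

    # golden-section refinement inside the bracketing interval
    a, b = grid[i - 1], grid[i + 1]
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = evaluate(c), evaluate(d)
    while b - a > log_tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = evaluate(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = evaluate(d)
    log_best, f_best = (c, fc) if fc < fd else (d, fd)
    return OptimumResult(10.0**log_best, float(sign * f_best), False, False, n_sim)


def affinity_density_heatmap(
    scenario: Scenario,
    kd_grid_m: Sequence[float],
    receptor_density_grid: Sequence[float],
    internalization_rate_per_min: float | None = None,
    t_end_h: float = 72.0,
    options: SolverOptions | None = None,
    cache: SimulationCache | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maximum inhibition over a (receptor density) x (Kd) grid.

    Returns ``(matrix, trace)``: the heatmap as a DataFrame indexed by
    receptors/cell with Kd columns, and the per-density optimal Kd and
    its maximum inhibition (the readout of how the affinity optimum
    tracks receptor density).
    """
    opts = options or SolverOptions()
    cache = cache or SimulationCache()
    if internalization_rate_per_min is not None:
        scenario = _set_by_path(scenario, "tissue.k_internalize_per_min",
                                internalization_rate_per_min)
    matrix = np.full((len(receptor_density_grid), len(kd_grid_m)), np.nan)
    for i, dens in enumerate(receptor_density_grid):
        sc_d = _set_by_path(scenario, "tissue.receptors_per_cell", float(dens))
        for j, kd in enumerate(kd_grid_m):
            sc = _set_by_path(sc_d, "agent.kd_receptor_m", float(kd))
            try:
                matrix[i, j] = outcomes.max_inhibition(
                    cache.run(sc, t_end_h, opts))
            except (IntegrationError, ValueError) as exc:
                log.warning("heatmap point dens=%g kd=%g failed: %s",
                            dens, kd, exc)
    df = pd.DataFrame(matrix, index=list(receptor_density_grid),
                      columns=list(kd_grid_m))
    df.index.name = "receptors_per_cell"
    df.columns.name = "kd_receptor_m"

    trace_rows = []
    for i, dens in enumerate(receptor_density_grid):
        sc_d = _set_by_path(scenario, "tissue.receptors_per_cell", float(dens))
        opt = optimal_affinity(
            sc_d, (min(kd_grid_m), max(kd_grid_m)),
            objective="min_avg_free_target",
            t_end_h=t_end_h, options=opts, cache=cache)
        sc_best = _set_by_path(sc_d, "agent.kd_receptor_m", opt.kd_m)
        mi = outcomes.max_inhibition(cache.run(sc_best, t_end_h, opts))
        trace_rows.append({"receptors_per_cell": float(dens),
                           "optimal_kd_m": opt.kd_m,
                           "max_inhibition_at_optimum": mi,
                           "on_bound": opt.on_bound})
    return df, pd.DataFrame(trace_rows)


def compare_strategies(
    scenario: Scenario,
    strategies: Iterable[str] = ("baseline", "optimal_kd", "cold_dose",
                                "cyto_half_life_100x", "catalytic"),
    k_cat_per_min: float = 2.35,
    t_end_h: float = 168.0,
    options: SolverOptions | None = None,
    cache: SimulationCache | None = None,
) -> pd.DataFrame:
    """Side-by-side comparison of engineering strategies on one scenario.

    Strategies: ``baseline`` (the scenario as given), ``optimal_kd``
    (receptor affinity re-optimized for delivery), ``cold_dose``
    (a cargo-free 10 kDa competitor co-dosed 1:1 with every warm dose),
    ``cyto_half_life_100x`` (degradation-resistant agent) and
    ``catalytic`` (same delivery, enzymatic target inactivation).
    """
    from .dosing import DoseEvent, DoseRegimen, DoseSpecies

    opts = options or SolverOptions()
    cache = cache or SimulationCache()
    rows = []
    for strategy in strategies:
        sc = scenario
        if strategy == "baseline":
            pass
        elif strategy == "optimal_kd":
            opt = optimal_affinity(scenario, t_end_h=min(t_end_h, 72.0),
                                   options=opts, cache=cache)
            sc = _set_by_path(scenario, "agent.kd_receptor_m", opt.kd_m)
        elif strategy == "cold_dose":
            sc = with_cold_dose(scenario)
        elif strategy == "cyto_half_life_100x":
            agent = replace(scenario.agent,
                            cytosolic_half_life_h=100 * scenario.agent.cytosolic_half_life_h)
            sc = scenario.replace(agent=agent)
        elif strategy == "catalytic":
            agent = replace(scenario.agent, mode=Mode.CATALYTIC,
                            k_cat_per_min=k_cat_per_min)
            sc = scenario.replace(agent=agent)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        traj = cache.run(sc, t_end_h, opts)
        from .dosing import plasma_auc
        rows.append({
            "strategy": strategy,
            "inhibitory_effect_h": outcomes.inhibitory_effect(traj),
            "max_inhibition": outcomes.max_inhibition(traj),
            "plasma_auc_M_h": plasma_auc(sc.regimen, DoseSpecies.WARM, t_end_h),
        })
    return pd.DataFrame(rows)


def with_cold_dose(
    scenario: Scenario,
    offset_h: float = 0.0,
    peak_ratio: float = 1.0,
    cold_mw_kda: float = 10.0,
) -> Scenario:
    """Add a cargo-free cold competitor to every warm dose.

    The cold agent shares the warm agent's receptor kinetics but carries
    no cargo and is smaller (10 kDa by default), so it extravasates and
    diffuses faster; its plasma profile mirrors the warm dose (same
    half-life, 1:1 peak unless ``peak_ratio`` differs).
    """
    from .dosing import DoseEvent, DoseRegimen, DoseSpecies

    regimen = scenario.regimen
    events = list(regimen.events)
    for ev in regimen.events_for(DoseSpecies.WARM):
        events.append(DoseEvent(ev.time_h + offset_h,
                                peak_ratio * ev.peak_plasma_concentration_m,
                                DoseSpecies.COLD))
    new_regimen = DoseRegimen(tuple(events),
                              half_life_warm_h=regimen.half_life_warm_h,
                              half_life_cold_h=regimen.half_life_warm_h)
    cold = replace(scenario.agent, molecular_weight_kda=cold_mw_kda,
                   is_cold=True)
    return scenario.replace(regimen=new_regimen, cold_agent=cold)
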