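"""Outcome metrics computed from a simulated trajectory.

Inhibition at a point is the fractional reduction of free, functional
cytosolic target below its pre-dose steady state; catalytically
inactivated target is gone from the free pool and therefore counts as
inhibited.  Tissue summaries are annular-volume-weighted averages over
the Krogh annulus (the capillary lumen is excluded by construction).

* maximum inhibition — the best volume-averaged inhibition at any
  single time point;
* inhibitory effect — the volume-averaged inhibition integrated over
  time (units: fraction x hours);
* time of maximum delivery — when the volume-averaged free target is at
  its minimum;
* penetration depth — how far from the capillary wall one must go to
  enclose a given fraction of all tissue-associated agent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import Trajectory
from .params import TargetSpec


@dataclass(frozen=True)
class OutcomeReport:
    """Summary metrics of one simulation."""

    max_inhibition: float
    t_max_inhibition_h: float
    inhibitory_effect_h: float
    t_max_delivery_h: float
    penetration_depth_50_um: float

    def to_dict(self) -> dict[str, float]:
        return {
            "max_inhibition": self.max_inhibition,
            "t_max_inhibition_h": self.t_max_inhibition_h,
            "inhibitory_effect_h": self.inhibitory_effect_h,
            "t_max_delivery_h": self.t_max_delivery_h,
            "penetration_depth_50_um": self.penetration_depth_50_um,
        }


def inhibition_field(traj: Trajectory, target: TargetSpec | None = None) -> np.ndarray:
    """Fractional inhibition 1 - T_free/T0 per (time, shell), in [0, 1]."""
    target = target or traj.scenario.target
    t0 = target.baseline_concentration_m
    if t0 <= 0:
        raise ValueError("baseline target concentration must be positive")
    return np.clip(1.0 - traj.fields["T_free"] / t0, 0.0, 1.0)


def average_inhibition(traj: Trajectory) -> np.ndarray:
    """Volume-averaged inhibition time series."""
    return traj.grid.average(inhibition_field(traj))


def max_inhibition(traj: Trajectory) -> float:
    """Highest volume-averaged inhibition at any single time point."""
    if len(traj.times_h) < 2:
        raise ValueError("trajectory needs at least two time points")
    return float(average_inhibition(traj).max())


def time_of_max_inhibition(traj: Trajectory) -> float:
    avg = average_inhibition(traj)
    return float(traj.times_h[int(np.argmax(avg))])


def inhibitory_effect(traj: Trajectory) -> float:
    """Time integral of the volume-averaged inhibition, fraction*hours."""
    return float(np.trapezoid(average_inhibition(traj), traj.times_h))


def time_of_max_delivery(traj: Trajectory, rel_drop_min: float = 1e-6) -> float:
    """Time at which the volume-averaged free target is at its minimum.

    Returns NaN for degenerate runs in which the free target never drops
    by more than ``rel_drop_min`` relative to baseline (e.g. zero dose).
    """
    t0 = traj.scenario.target.baseline_concentration_m
    avg = traj.grid.average(traj.fields["T_free"])
    i = int(np.argmin(avg))
    if t0 <= 0 or (t0 - avg[i]) / t0 < rel_drop_min:
        return math.nan
    return float(traj.times_h[i])


def penetration_depth(
    traj: Trajectory,
    mass_fraction: float = 0.5,
    t_h: float | None = None,
) -> float:
    """Smallest depth (um from the capillary wall) whose shells hold at
    least ``mass_fraction`` of the tissue-associated agent at ``t_h``.

    All agent compartments count (interstitial, surface-bound, cytosolic
    free and complexed, on a common tissue basis) with annular volume
    weighting; the cumulative mass profile is interpolated linearly in
    depth.  Defaults to the time of maximum delivery.  Returns NaN when
    no agent is present in the tissue.
    """
    if not 0.0 < mass_fraction < 1.0:
        if mass_fraction == 1.0:
            return float(traj.grid.edges_um[-1] - traj.grid.edges_um[0])
        raise ValueError("mass_fraction must lie in (0, 1]")
    if t_h is None:
        t_h = time_of_max_delivery(traj)
        if math.isnan(t_h):
            t_h = traj.times_h[int(np.argmax(traj.agent_mass_per_length()))]
    i_t = int(np.argmin(np.abs(traj.times_h - t_h)))
    conc = traj.agent_tissue_concentration()[i_t]
    masses = conc * traj.grid.shell_areas_um2
    total = masses.sum()
    if total <= 0:
        return math.nan
    cum = np.concatenate([[0.0], np.cumsum(masses)]) / total
    depths = traj.grid.edges_um - traj.grid.edges_um[0]
    return float(np.interp(mass_fraction, cum, depths))


def report(traj: Trajectory) -> OutcomeReport:
    """All outcome metrics of one trajectory."""
    return OutcomeReport(
        max_inhibition=max_inhibition(traj),
        t_max_inhibition_h=time_of_max_inhibition(traj),
        inhibitory_effect_h=inhibitory_effect(traj),
        t_max_delivery_h=time_of_max_delivery(traj),
        penetration_depth_50_um=penetration_depth(traj),
    )
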