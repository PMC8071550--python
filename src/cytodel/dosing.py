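"""Plasma pharmacokinetics: bolus dosing and mono-exponential clearance.

Plasma concentration is a forcing function of the tissue model — tissue
uptake does not feed back on it.  Each bolus raises plasma by its peak
concentration instantaneously and decays with the species' half-life;
repeated doses superpose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

LN2 = math.log(2.0)


class DoseSpecies(str, Enum):
    WARM = "warm"
    COLD = "cold"


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous bolus.

    ``peak_plasma_concentration_m`` is the plasma concentration the dose
    produces at its injection time (superposed on whatever remains of
    earlier doses).
    """

    time_h: float
    peak_plasma_concentration_m: float
    species: DoseSpecies = DoseSpecies.WARM

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("dose time must be non-negative")
        if self.peak_plasma_concentration_m < 0:
            raise ValueError("dose concentration must be non-negative")
        object.__setattr__(self, "species", DoseSpecies(self.species))


@dataclass(frozen=True)
class DoseRegimen:
    """An ordered series of boluses with per-species plasma half-lives.

    The cold species, when used, follows the warm plasma profile shape:
    by convention its half-life equals the warm one unless overridden.
    """

    events: tuple[DoseEvent, ...]
    half_life_warm_h: float
    half_life_cold_h: float | None = None

    def __post_init__(self) -> None:
        events = tuple(sorted((DoseEvent(**e) if isinstance(e, dict) else e
                               for e in self.events), key=lambda e: e.time_h))
        object.__setattr__(self, "events", events)
        if self.half_life_warm_h <= 0:
            raise ValueError("plasma half-life must be positive")
        if self.half_life_cold_h is None:
            object.__setattr__(self, "half_life_cold_h", self.half_life_warm_h)

    def half_life_for(self, species: DoseSpecies) -> float:
        return (self.half_life_warm_h if species is DoseSpecies.WARM
                else self.half_life_cold_h)

    def events_for(self, species: DoseSpecies) -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events if e.species is species)

    def event_times(self) -> np.ndarray:
        """Unique dose times, used as integrator restart points."""
        return np.unique([e.time_h for e in self.events])


def plasma_concentration(
    regimen: DoseRegimen,
    species: DoseSpecies | str,
    t_h,
):
    """Plasma concentration (M) of one species at time(s) ``t_h``.

    Right-continuous superposition of exponentially decaying boluses:
    C(t) = sum over events with t_event <= t of peak * 2^-((t-t_event)/t_half).
    """
    species = DoseSpecies(species)
    t = np.asarray(t_h, dtype=float)
    thalf = regimen.half_life_for(species)
    out = np.zeros_like(t)
    for ev in regimen.events_for(species):
        dt = t - ev.time_h
        mask = dt >= 0
        out = out + np.where(mask, ev.peak_plasma_concentration_m
                             * np.exp2(-np.clip(dt, 0, None) / thalf), 0.0)
    return out if out.ndim else float(out)


def plasma_auc(
    regimen: DoseRegimen,
    species: DoseSpecies | str,
    t_end_h: float,
) -> float:
    """Plasma exposure, integral of concentration over [0, t_end], M*h.

    Closed form: each bolus contributes peak * tau * (1 - 2^-(dt/t_half))
    with tau = t_half/ln2, truncated at ``t_end_h``.
    """
    species = DoseSpecies(species)
    events = regimen.events_for(species)
    if events and t_end_h < max(e.time_h for e in events):
        raise ValueError("t_end_h must be at or after the last dose event")
    thalf = regimen.half_life_for(species)
    tau = thalf / LN2
    total = 0.0
    for ev in events:
        dt = t_end_h - ev.time_h
        total += ev.peak_plasma_concentration_m * tau * (1.0 - math.exp2(-dt / thalf))
    return total


def make_regimen(
    pattern: str = "single",
    peak_m: float = 1e-6,
    half_life_h: float = 2.55,
    interval_h: float | None = None,
    n_doses: int = 1,
    cold_offset_h: float | None = None,
    cold_peak_m: float | None = None,
    half_life_cold_h: float | None = None,
) -> DoseRegimen:
    """Build a warm (and optionally warm+cold) dosing regimen.

    ``pattern`` is ``"single"`` or ``"repeated"``; repeated dosing places
    ``n_doses`` boluses ``interval_h`` apart starting at t=0.  If
    ``cold_offset_h`` is given, every warm dose is paired with a cold
    dose at ``time + offset`` (1:1 peak ratio unless ``cold_peak_m`` is
    set); the cold plasma profile uses the warm half-life by default, so
    warm and cold doses share the same plasma concentration profile.
    """
    if pattern not in ("single", "repeated"):
        raise ValueError(f"unknown dosing pattern {pattern!r}")
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    if pattern == "single":
        n_doses = 1
        interval_h = 0.0
    elif interval_h is None or interval_h <= 0:
        raise ValueError("repeated dosing requires a positive interval_h")
    events: list[DoseEvent] = []
    for i in range(n_doses):
        t = i * (interval_h or 0.0)
        events.append(DoseEvent(t, peak_m, DoseSpecies.WARM))
        if cold_offset_h is not None:
            events.append(DoseEvent(t + cold_offset_h,
                                    cold_peak_m if cold_peak_m is not None else peak_m,
                                    DoseSpecies.COLD))
    return DoseRegimen(tuple(events), half_life_warm_h=half_life_h,
                       half_life_cold_h=half_life_cold_h)
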