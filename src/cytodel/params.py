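"""Parameter containers for the delivery model.

Three frozen dataclasses describe a simulation scenario: the engineered
agent (:class:`AgentSpec`), the tissue it is delivered to
(:class:`TissueSpec`) and the cytosolic target it engages
(:class:`TargetSpec`).  :class:`Rates` collects every derived rate
constant, in per-second units, that the reaction network needs.

Units are carried in field names (``_h`` hours, ``_um`` micrometers,
``_m`` molar, and so on) so that configuration files are unambiguous.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import Enum

from .units import copies_to_molar, receptors_to_molar, scale_transport

LN2 = math.log(2.0)


class Mode(str, Enum):
    """Mechanism of action of the delivered cargo.

    ``binder`` inhibits by stoichiometric occupancy of the target;
    ``catalytic`` turns over and inactivates target molecules at
    ``k_cat`` while being released intact.
    """

    BINDER = "binder"
    CATALYTIC = "catalytic"


@dataclass(frozen=True)
class AgentSpec:
    """An engineered targeting agent (protein or peptide).

    Parameters
    ----------
    molecular_weight_kda : float
        Size of the agent; sets its transport coefficients through the
        size-scaling laws.
    kd_receptor_m : float
        Equilibrium dissociation constant for the cell-surface receptor.
        The off-rate is derived as ``kon * Kd``.
    kon_receptor_m_s : float
        Association rate constant for the receptor, 1/(M s).
    plasma_half_life_h : float
        Mono-exponential plasma clearance half-life.
    cytosolic_half_life_h : float
        Degradation half-life of the free agent in the cytosol.
    mode : Mode
        ``binder`` or ``catalytic``.
    k_cat_per_min : float
        Catalytic turnover of the agent-target complex; must be 0 in
        binder mode.
    kd_target_m, kon_target_m_s : float
        Cytosolic target engagement kinetics.
    escape_fraction : float
        Fraction of internalized agent that escapes endosomes into the
        cytosol; the remainder is degraded in the endolysosomal route.
    is_cold : bool
        A cold agent carries no cargo: it competes for surface receptor
        but contributes no cytosolic species.
    """

    molecular_weight_kda: float = 70.0
    kd_receptor_m: float = 68e-12
    kon_receptor_m_s: float = 1e5
    plasma_half_life_h: float = 2.55
    cytosolic_half_life_h: float = 6.0
    mode: Mode = Mode.BINDER
    k_cat_per_min: float = 0.0
    kd_target_m: float = 1e-10
    kon_target_m_s: float = 1e6
    escape_fraction: float = 0.02
    is_cold: bool = False

    def __post_init__(self) -> None:
        if self.molecular_weight_kda <= 0:
            raise ValueError("molecular_weight_kda must be positive")
        for name in ("kd_receptor_m", "kon_receptor_m_s", "plasma_half_life_h",
                     "cytosolic_half_life_h", "kd_target_m", "kon_target_m_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ValueError("escape_fraction must lie in [0, 1]")
        mode = Mode(self.mode)
        object.__setattr__(self, "mode", mode)
        if self.k_cat_per_min < 0:
            raise ValueError("k_cat_per_min must be non-negative")
        # catalytic mode with k_cat = 0 is allowed and reduces exactly to
        # binder behaviour; the converse (a binder with k_cat > 0) is not
        if mode is Mode.BINDER and self.k_cat_per_min != 0.0:
            raise ValueError("binder mode requires k_cat_per_min == 0")
        koff = self.kon_receptor_m_s * self.kd_receptor_m
        if not math.isfinite(koff) or koff <= 0:
            raise ValueError("derived receptor off-rate is not finite/positive")

    @property
    def koff_receptor_s(self) -> float:
        """Receptor off-rate kon*Kd, 1/s."""
        return self.kon_receptor_m_s * self.kd_receptor_m

    @property
    def koff_target_s(self) -> float:
        """Target off-rate kon*Kd, 1/s."""
        return self.kon_target_m_s * self.kd_target_m

    def with_kd(self, kd_receptor_m: float) -> "AgentSpec":
        """Copy of this agent with a different receptor affinity."""
        return dataclasses.replace(self, kd_receptor_m=kd_receptor_m)


@dataclass(frozen=True)
class TissueSpec:
    """Krogh-cylinder tissue: geometry, transport and receptor biology.

    ``vascular_permeability_cm_s`` and ``interstitial_diffusivity_cm2_s``
    are reference values measured at ``reference_mw_kda``; the transport
    coefficients of a particular agent are obtained by size scaling.
    ``fluid_velocity_at_wall_um_s`` is the interstitial fluid velocity at
    the capillary wall; zero means diffusion-only transport (a tumor with
    collapsed lymphatics), nonzero adds radial convection that drains at
    the outer (lymphatic) boundary.
    """

    capillary_radius_um: float = 8.0
    krogh_radius_um: float = 108.0
    void_fraction: float = 0.2
    vascular_permeability_cm_s: float = 3e-7
    interstitial_diffusivity_cm2_s: float = 1e-8
    reference_mw_kda: float = 70.0
    fluid_velocity_at_wall_um_s: float = 0.0
    reflection_coefficient: float = 0.9
    cell_density_per_ml: float = 2.9e8
    receptors_per_cell: float = 5.4e5
    k_internalize_per_min: float = 0.002
    receptor_steady_state: bool = True
    outer_boundary_sink: bool = True

    def __post_init__(self) -> None:
        if self.capillary_radius_um <= 0:
            raise ValueError("capillary_radius_um must be positive")
        if self.krogh_radius_um <= self.capillary_radius_um:
            raise ValueError("krogh_radius_um must exceed capillary_radius_um")
        if not 0.0 < self.void_fraction < 1.0:
            raise ValueError("void_fraction must lie in (0, 1)")
        if self.fluid_velocity_at_wall_um_s < 0:
            raise ValueError("fluid velocity must be non-negative")
        if not 0.0 <= self.reflection_coefficient <= 1.0:
            raise ValueError("reflection_coefficient must lie in [0, 1]")
        if self.cell_density_per_ml < 0 or self.receptors_per_cell < 0:
            raise ValueError("cell density and receptor count must be non-negative")
        if self.vascular_permeability_cm_s <= 0 or self.interstitial_diffusivity_cm2_s <= 0:
            raise ValueError("transport coefficients must be positive")
        if self.k_internalize_per_min < 0:
            raise ValueError("internalization rate must be non-negative")

    @property
    def receptor_concentration_m(self) -> float:
        """Total receptor pool, mol per liter of whole tissue."""
        return receptors_to_molar(self.receptors_per_cell, self.cell_density_per_ml)

    def transport_for(self, agent: AgentSpec) -> tuple[float, float]:
        """(P, D) of ``agent`` in this tissue after size scaling."""
        return scale_transport(
            self.vascular_permeability_cm_s,
            self.interstitial_diffusivity_cm2_s,
            self.reference_mw_kda,
            agent.molecular_weight_kda,
        )


@dataclass(frozen=True)
class TargetSpec:
    """The cytosolic target protein.

    The synthesis rate is chosen so that the pre-dose steady state equals
    ``copies_per_cell``: k_syn = T0 * ln2 / target_half_life.
    """

    copies_per_cell: float = 1e4
    cytosol_volume_pl: float = 1.0
    target_half_life_h: float = 24.0

    def __post_init__(self) -> None:
        if self.copies_per_cell < 0:
            raise ValueError("copies_per_cell must be non-negative")
        if self.cytosol_volume_pl <= 0:
            raise ValueError("cytosol_volume_pl must be positive")
        if self.target_half_life_h <= 0:
            raise ValueError("target_half_life_h must be positive")

    @property
    def baseline_concentration_m(self) -> float:
        """Pre-dose free-target concentration, mol/L cytosol."""
        return copies_to_molar(self.copies_per_cell, self.cytosol_volume_pl)


@dataclass(frozen=True)
class Rates:
    """Derived per-second rate constants for one agent in one scenario.

    Interstitial and surface species are expressed per liter of whole
    tissue; cytosolic species per liter of cytosol.  ``phi`` is the
    cytosol volume fraction converting between the two bases, ``eps``
    the interstitial (void) volume fraction.
    """

    kon_r: float
    koff_r: float
    ke: float
    escape: float
    kdec_cyt: float
    kon_t: float
    koff_t: float
    kcat: float
    ksyn: float
    kdec_target: float
    eps: float
    phi: float
    receptor_total_m: float
    target0_m: float
    permeability_cm_s: float
    diffusivity_cm2_s: float


def derive_rates(agent: AgentSpec, tissue: TissueSpec, target: TargetSpec) -> Rates:
    """Assemble all rate constants (1/s) for the reaction network."""
    p, d = tissue.transport_for(agent)
    phi = tissue.cell_density_per_ml * target.cytosol_volume_pl * 1e-12 * 1e3
    t0 = target.baseline_concentration_m
    kdec_target = LN2 / (target.target_half_life_h * 3600.0)
    return Rates(
        kon_r=agent.kon_receptor_m_s,
        koff_r=agent.koff_receptor_s,
        ke=tissue.k_internalize_per_min / 60.0,
        escape=agent.escape_fraction,
        kdec_cyt=LN2 / (agent.cytosolic_half_life_h * 3600.0),
        kon_t=agent.kon_target_m_s,
        koff_t=agent.koff_target_s,
        kcat=agent.k_cat_per_min / 60.0,
        ksyn=t0 * kdec_target,
        kdec_target=kdec_target,
        eps=tissue.void_fraction,
        phi=phi,
        receptor_total_m=tissue.receptor_concentration_m,
        target0_m=t0,
        permeability_cm_s=p,
        diffusivity_cm2_s=d,
    )


@dataclass(frozen=True)
class Scenario:
    """A complete simulation setup: agent, tissue, target and dosing.

    ``cold_agent`` is optional; when present the regimen's cold dose
    events drive a second, cargo-free species that competes for the
    surface receptor.
    """

    agent: AgentSpec
    tissue: TissueSpec
    target: TargetSpec
    regimen: "DoseRegimen" = None  # type: ignore[assignment]
    cold_agent: AgentSpec | None = None

    def replace(self, **kwargs) -> "Scenario":
        return dataclasses.replace(self, **kwargs)


def canonical_dict(obj) -> dict:
    """Recursively convert specs to plain dicts for hashing/serialization."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: canonical_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (list, tuple)):
        return [canonical_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: canonical_dict(v) for k, v in obj.items()}
    return obj
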