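"""cytodel: Krogh-cylinder modeling of in vivo cytosolic protein delivery.

A reaction-diffusion-convection model of a therapeutic protein or
peptide extravasating from a capillary, penetrating tissue, binding a
cell-surface receptor, escaping endosomes and engaging a cytosolic
target — either blocking it stoichiometrically or inactivating it
catalytically.  The package bundles tissue/agent presets, dosing-regimen
pharmacokinetics, outcome metrics and in silico experiment drivers
(affinity sweeps, receptor-density heatmaps, strategy comparisons).
"""

from .dosing import (DoseEvent, DoseRegimen, DoseSpecies, make_regimen,
                     plasma_auc, plasma_concentration)
from .engine import (IntegrationError, SolverOptions, Trajectory, simulate)
from .grid import RadialGrid, build_grid
from .kinetics import initial_state, reaction_terms
from .outcomes import (OutcomeReport, inhibition_field, inhibitory_effect,
                       max_inhibition, penetration_depth, report,
                       time_of_max_delivery)
from .params import (AgentSpec, Mode, Scenario, TargetSpec, TissueSpec,
                     derive_rates)
from .units import copies_to_molar, receptors_to_molar, scale_transport

__version__ = "0.1.0"

__all__ = [
    "AgentSpec", "TissueSpec", "TargetSpec", "Scenario", "Mode",
    "DoseEvent", "DoseRegimen", "DoseSpecies", "make_regimen",
    "plasma_concentration", "plasma_auc",
    "RadialGrid", "build_grid", "initial_state", "reaction_terms",
    "SolverOptions", "Trajectory", "simulate", "IntegrationError",
    "OutcomeReport", "inhibition_field", "max_inhibition",
    "inhibitory_effect", "time_of_max_delivery", "penetration_depth",
    "report", "derive_rates",
    "receptors_to_molar", "copies_to_molar", "scale_transport",
    "load_preset", "load_config", "__version__",
]


def load_preset(name: str):
    """Load a bundled scenario preset by name (lazy import)."""
    from .config import load_preset as _lp
    return _lp(name)


def load_config(path):
    """Load and validate a scenario configuration file (lazy import)."""
    from .config import load_config as _lc
    return _lc(path)
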