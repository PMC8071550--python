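"""Unit conversions and size-scaling laws.

The simulation works in molar concentrations throughout.  Cell-biology
inputs (receptors/cell, copies/cell) are converted here, and transport
coefficients measured for a reference molecular weight are rescaled to
other sizes with simple power laws.
"""

from __future__ import annotations

N_AVOGADRO = 6.02214076e23  # 1/mol

#: Exponent of the molecular-weight scaling of interstitial diffusivity.
#: Stokes-Einstein on a compact globule: hydrodynamic radius ~ MW^(1/3).
DIFFUSIVITY_MW_EXPONENT = 1.0 / 3.0

#: Exponent for vascular permeability.  Trans-endothelial transport is
#: hindered pore diffusion and falls off much faster with size than free
#: diffusion; 0.65 reproduces the several-fold permeability gap between
#: a few-kDa solute and a 70 kDa dextran in tumor vessels.
PERMEABILITY_MW_EXPONENT = 0.65


def receptors_to_molar(
    receptors_per_cell: float,
    cell_density_per_ml: float,
    basis_volume_fraction: float = 1.0,
) -> float:
    """Convert a surface-receptor count into a molar concentration.

    Parameters
    ----------
    receptors_per_cell : float
        Copies of the receptor on one cell surface.
    cell_density_per_ml : float
        Cells per milliliter of tissue.
    basis_volume_fraction : float, optional
        Volume fraction of the reference compartment the concentration
        is expressed per.  The default 1.0 expresses receptors per liter
        of whole tissue, the convention used by the model equations.

    Returns
    -------
    float
        Receptor concentration in mol/L of the chosen basis volume.
    """
    if receptors_per_cell < 0 or cell_density_per_ml < 0:
        raise ValueError("receptor count and cell density must be non-negative")
    if not 0 < basis_volume_fraction <= 1:
        raise ValueError("basis_volume_fraction must be in (0, 1]")
    per_liter = receptors_per_cell * cell_density_per_ml * 1e3  # cells/mL -> cells/L
    return per_liter / N_AVOGADRO / basis_volume_fraction


def copies_to_molar(copies_per_cell: float, cytosol_volume_pl: float) -> float:
    """Molar concentration of a cytosolic protein present at
    ``copies_per_cell`` in a cytosol of ``cytosol_volume_pl`` picoliters.

    About 6000 copies in a 1 pL cytosol is 10 nM.
    """
    if copies_per_cell < 0:
        raise ValueError("copies_per_cell must be non-negative")
    if cytosol_volume_pl <= 0:
        raise ValueError("cytosol volume must be positive")
    return copies_per_cell / (N_AVOGADRO * cytosol_volume_pl * 1e-12)


def scale_transport(
    permeability_ref_cm_s: float,
    diffusivity_ref_cm2_s: float,
    mw_ref_kda: float,
    mw_kda: float,
) -> tuple[float, float]:
    """Rescale vascular permeability and interstitial diffusivity from a
    reference molecular weight to another.

    D scales as (MW_ref/MW)^(1/3); P with the steeper exponent 0.6, so a
    small peptide both extravasates and diffuses faster than a protein.

    Returns
    -------
    (P, D) : tuple of float
        Permeability in cm/s and diffusivity in cm^2/s at ``mw_kda``.
    """
    if mw_kda <= 0 or mw_ref_kda <= 0:
        raise ValueError("molecular weights must be positive")
    ratio = mw_ref_kda / mw_kda
    p = permeability_ref_cm_s * ratio**PERMEABILITY_MW_EXPONENT
    d = diffusivity_ref_cm2_s * ratio**DIFFUSIVITY_MW_EXPONENT
    return p, d
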