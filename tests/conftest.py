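"""Shared fixtures: bundled scenarios and cached reference trajectories.

Simulations for unit/property tests run on a coarser 40-shell grid to
keep the suite fast; the acceptance tests use the full default grid.
"""

from __future__ import annotations

import pytest

from cytodel import SolverOptions, load_preset, simulate

FAST = SolverOptions(n_shells=40)


@pytest.fixture(scope="session")
def tumor_noconv():
    return load_preset("tumor_protein_noconv")


@pytest.fixture(scope="session")
def tumor_conv():
    return load_preset("tumor_protein_conv")


@pytest.fixture(scope="session")
def tumor_peptide():
    return load_preset("tumor_peptide")


@pytest.fixture(scope="session")
def muscle():
    return load_preset("muscle_protein")


@pytest.fixture(scope="session")
def protein_traj(tumor_noconv):
    """Default protein, single 1 uM dose, 72 h, coarse grid."""
    return simulate(tumor_noconv, t_end_h=72.0, options=FAST)


@pytest.fixture(scope="session")
def peptide_traj(tumor_peptide):
    return simulate(tumor_peptide, t_end_h=72.0, options=FAST)
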