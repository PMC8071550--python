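"""Radial finite-volume grid over the Krogh annulus."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import TissueSpec


@dataclass(frozen=True)
class RadialGrid:
    """Uniform shells between the capillary wall and the Krogh radius.

    All lengths in micrometers.  ``edges_um`` has ``n_shells + 1``
    entries; shell i spans [edges[i], edges[i+1]].  Cross-section areas
    (volume per unit capillary length) carry the annular weighting used
    for every volume average in the model.
    """

    edges_um: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_um, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two shell edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("shell edges must be strictly increasing")
        object.__setattr__(self, "edges_um", edges)

    @property
    def n_shells(self) -> int:
        return self.edges_um.size - 1

    @property
    def centers_um(self) -> np.ndarray:
        return 0.5 * (self.edges_um[:-1] + self.edges_um[1:])

    @property
    def depth_um(self) -> np.ndarray:
        """Distance of shell centers from the capillary wall."""
        return self.centers_um - self.edges_um[0]

    @property
    def spacing_um(self) -> np.ndarray:
        return np.diff(self.edges_um)

    @property
    def shell_areas_um2(self) -> np.ndarray:
        """pi*(r_{i+1}^2 - r_i^2): shell volume per unit length."""
        return np.pi * np.diff(self.edges_um**2)

    @property
    def volume_weights(self) -> np.ndarray:
        """Shell areas normalized to sum to 1 (tissue volume average)."""
        a = self.shell_areas_um2
        return a / a.sum()

    def average(self, field: np.ndarray) -> np.ndarray:
        """Tissue-volume average of a per-shell field (last axis = shell)."""
        return np.asarray(field) @ self.volume_weights


def build_grid(tissue: TissueSpec, n_shells: int = 100) -> RadialGrid:
    """Uniformly spaced radial grid for a tissue preset."""
    if n_shells < 4:
        raise ValueError("n_shells must be at least 4")
    edges = np.linspace(tissue.capillary_radius_um, tissue.krogh_radius_um,
                        n_shells + 1)
    return RadialGrid(edges)
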