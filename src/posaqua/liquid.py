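"""In-memory containers for rigid-body liquid configurations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO
from .forcefield import MoleculeSpec

__all__ = ["RigidMolecule", "LiquidConfiguration"]


@dataclass
class RigidMolecule:
    """A rigid molecule posed in the lab frame.

    ``coords`` are world-frame site positions (Å) consistent with the
    internal geometry of ``spec`` (rigid body: only rotated/translated).
    """
    spec: MoleculeSpec
    coords: np.ndarray

    @classmethod
    def from_pose(cls, spec: MoleculeSpec, position: np.ndarray,
                  rotation: np.ndarray | None = None) -> "RigidMolecule":
        R = np.eye(3) if rotation is None else rotation
        return cls(spec=spec, coords=spec.coords @ R.T + position)

    @property
    def reference_site(self) -> int:
        """Site used for minimum-image/cutoff bookkeeping (first heavy atom)."""
        for i, s in enumerate(self.spec.sites):
            if s.element != "H":
                return i
        return 0


@dataclass
class LiquidConfiguration:
    """A solute plus N rigid waters in a cubic box of edge ``box_edge`` Å.

    ``water_coords`` has shape (n_waters, n_water_sites, 3).  ``solute`` may
    be None for neat-water boxes.
    """
    solute: MoleculeSpec | None
    solute_coords: np.ndarray | None
    water: MoleculeSpec
    water_coords: np.ndarray
    box_edge: float
    meta: dict = field(default_factory=dict)

    @property
    def n_waters(self) -> int:
        return int(self.water_coords.shape[0])

    @property
    def total_mass(self) -> float:
        m = self.n_waters * self.water.mass
        if self.solute is not None:
            m += self.solute.mass
        return m

    @property
    def density(self) -> float:
        """Mass density in g/cm^3."""
        v_cm3 = self.box_edge**3 * 1.0e-24
        return self.total_mass / (AVOGADRO * v_cm3)

    def copy(self) -> "LiquidConfiguration":
        return LiquidConfiguration(
            solute=self.solute,
            solute_coords=None if self.solute_coords is None
            else self.solute_coords.copy(),
            water=self.water,
            water_coords=self.water_coords.copy(),
            box_edge=self.box_edge,
            meta=dict(self.meta),
        )

    # --- flat views used by the MC kernels and analysis ---
    def flat_coords(self) -> np.ndarray:
        parts = []
        if self.solute is not None:
            parts.append(self.solute_coords)
        parts.append(self.water_coords.reshape(-1, 3))
        return np.concatenate(parts, axis=0)

    def molecules(self):
        """Yield RigidMolecule views (solute first if present)."""
        if self.solute is not None:
            yield RigidMolecule(self.solute, self.solute_coords)
        for i in range(self.n_waters):
            yield RigidMolecule(self.water, self.water_coords[i])


def minimum_image(d: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Apply the cubic minimum-image convention to displacement vectors."""
    if box_edge is None:
        return d
    return d - box_edge * np.rint(d / box_edge)
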