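"""Quantum system container: nuclei, embedding charges, particles, bases."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ..constants import ATOMIC_NUMBER, BOHR_PER_ANGSTROM
from .basis import BasisSet

__all__ = ["QuantumSystem", "add_embedding"]


@dataclass
class QuantumSystem:
    """Nuclei + optional embedding point charges + quantum particles.

    Positions are stored in Å at the interface; integrals convert to bohr.
    The electron sector is closed-shell (even count) or a single particle;
    at most one positron is supported.
    """
    name: str
    elements: list[str]
    coords: np.ndarray                      # (n_atoms, 3) Å
    n_electrons: int
    n_positrons: int = 0
    electron_basis: BasisSet | None = None
    positron_basis: BasisSet | None = None
    embedding_coords: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3)))
    embedding_charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nuclear_charges: np.ndarray | None = None  # default: atomic numbers
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if self.nuclear_charges is None:
            self.nuclear_charges = np.array(
                [float(ATOMIC_NUMBER[e]) for e in self.elements])
        else:
            self.nuclear_charges = np.asarray(self.nuclear_charges, float)
        if self.n_electrons < 0 or self.n_positrons not in (0, 1):
            raise ValueError("need n_electrons >= 0 and n_positrons in {0,1}")
        if self.n_electrons > 1 and self.n_electrons % 2:
            raise ValueError("electron sector must be closed-shell (even) "
                             "or a single particle")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def coords_bohr(self) -> np.ndarray:
        return self.coords * BOHR_PER_ANGSTROM

    def all_charges_bohr(self):
        """Stacked (centers_bohr, signed charges): nuclei then embedding."""
        centers = np.vstack([self.coords_bohr(),
                             np.asarray(self.embedding_coords).reshape(-1, 3)
                             * BOHR_PER_ANGSTROM])
        charges = np.concatenate([self.nuclear_charges,
                                  self.embedding_charges])
        return centers, charges

    def nuclear_repulsion(self) -> float:
        """Classical Coulomb energy of nuclei + embedding charges (hartree)."""
        centers, charges = self.all_charges_bohr()
        e = 0.0
        for i in range(len(charges)):
            for j in range(i + 1, len(charges)):
                r = np.linalg.norm(centers[i] - centers[j])
                e += charges[i] * charges[j] / r
        return e

    def without_positron(self) -> "QuantumSystem":
        return replace(self, n_positrons=0, name=self.name + "(parent)")

    def total_charge(self) -> float:
        return (float(self.nuclear_charges.sum())
                + float(self.embedding_charges.sum())
                - self.n_electrons + self.n_positrons)


def add_embedding(system: QuantumSystem, charges, positions_angstrom) -> QuantumSystem:
    """Return a new system with extra point charges in the Hamiltonians.

    Charges contribute with particle-appropriate sign to both one-body
    Hamiltonians and to the classical energy offset.  Warns when a charge
    sits within 1 Å of a QM atom.
    """
    charges = np.asarray(charges, float)
    pos = np.asarray(positions_angstrom, float).reshape(-1, 3)
    if len(pos):
        d = np.linalg.norm(system.coords[:, None, :] - pos[None, :, :],
                           axis=-1)
        if d.min() < 1.0:
            warnings.warn(f"embedding charge within {d.min():.2f} Å of a QM "
                          "atom", stacklevel=2)
    return replace(
        system,
        embedding_coords=np.vstack([system.embedding_coords, pos]),
        embedding_charges=np.concatenate([system.embedding_charges, charges]),
    )
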