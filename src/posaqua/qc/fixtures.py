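"""Registry of tiny quantum fixtures with known properties.

These are the systems the test-suite leans on: one-particle systems with
exact charge-conjugation partners, small closed-shell molecules, a
water+positron system, a hand-settable second-order self-energy model,
and a strongly dipolar diatomic (LiH-like) that binds a positron already
at the mean-field level.
"""

from __future__ import annotations

import numpy as np

from ..constants import ANGSTROM_PER_BOHR
from ..props import P2Workspace
from .basis import BasisSet, build_even_tempered, minimal_basis_shells
from .system import QuantumSystem

__all__ = ["toy_quantum_registry", "WATER_GEOMETRY"]

# gas-phase-like water geometry (Å)
WATER_GEOMETRY = [("O", (0.0, 0.0, 0.1173)),
                  ("H", (0.0, 0.7572, -0.4692)),
                  ("H", (0.0, -0.7572, -0.4692))]


def _one_particle_basis():
    return build_even_tempered(0.03, 2.7, 9, [[0.0, 0.0, 0.0]], "sp")


def _electron_on_plus() -> QuantumSystem:
    return QuantumSystem("electron@+1", ["H"], np.zeros((1, 3)),
                         n_electrons=1, electron_basis=_one_particle_basis())


def _positron_on_minus() -> QuantumSystem:
    return QuantumSystem("positron@-1", ["H"], np.zeros((1, 3)),
                         n_electrons=0, n_positrons=1,
                         positron_basis=_one_particle_basis(),
                         nuclear_charges=np.array([-1.0]))


def _mirror_pair():
    """Two systems exactly related by charge conjugation."""
    return _electron_on_plus(), _positron_on_minus()


def _h2() -> QuantumSystem:
    r = 1.4 * ANGSTROM_PER_BOHR
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
    basis = BasisSet(minimal_basis_shells("H", [0, 0, 0])
                     + minimal_basis_shells("H", [0, 0, 1.4]))
    return QuantumSystem("H2", ["H", "H"], coords, n_electrons=2,
                         electron_basis=basis)


def _water(n_positrons: int = 0) -> QuantumSystem:
    elements = [a for a, _ in WATER_GEOMETRY]
    coords = np.array([x for _, x in WATER_GEOMETRY])
    shells = []
    for el, xyz in zip(elements, coords):
        shells.extend(minimal_basis_shells(el, xyz / ANGSTROM_PER_BOHR))
    pb = None
    if n_positrons:
        pb = build_even_tempered(1.6e-3, 3.0, 7,
                                 [coords[0] / ANGSTROM_PER_BOHR], "sp")
    return QuantumSystem("water" + ("+e+" if n_positrons else ""),
                         elements, coords, n_electrons=10,
                         n_positrons=n_positrons,
                         electron_basis=BasisSet(shells), positron_basis=pb)


def _lih_plus_positron() -> QuantumSystem:
    """LiH-like strongly dipolar diatomic (~6 D): the classic mean-field
    positron binder.  Positron basis spans both centers."""
    r = 1.60  # Å
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
    shells = (minimal_basis_shells("Li", [0, 0, 0])
              + minimal_basis_shells("H", np.array([0, 0, r])
                                     / ANGSTROM_PER_BOHR))
    pb = build_even_tempered(2e-3, 3.2, 8,
                             coords / ANGSTROM_PER_BOHR, "sp")
    return QuantumSystem("LiH+e+", ["Li", "H"], coords, n_electrons=4,
                         n_positrons=1, electron_basis=BasisSet(shells),
                         positron_basis=pb)


def _model_p2() -> P2Workspace:
    """Hand-set second-order self-energy model: 2 electron orbitals
    (1 occupied, 1 virtual), 2 positron orbitals (SOMO + 1 virtual)."""
    return P2Workspace(
        eps_i=np.array([-0.50]),
        eps_a=np.array([0.30]),
        eps_p=-0.020,
        eps_q=np.array([0.15]),
        v_pair=np.array([[[0.040]]]),
        v_relax=np.array([[0.025]]),
        spin_factor=2.0,
    )


def toy_quantum_registry() -> dict:
    return {
        "electron@+1": _electron_on_plus,
        "positron@-1": _positron_on_minus,
        "mirror_pair": _mirror_pair,
        "h2": _h2,
        "water": _water,
        "water+e+": lambda: _water(1),
        "lih+e+": _lih_plus_positron,
        "model_p2": _model_p2,
    }
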