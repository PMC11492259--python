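"""Embedded rigid-body force-field tables.

Waters use the SPC/E model (single LJ site on O, charges -0.8476/+0.4238 e,
rigid r(OH)=1.0 Å, HOH=109.47°).  The zwitterionic amino-acid solutes carry
OPLS-AA-style site parameters on MMFF-optimized stand-in geometries; the
small charge adjustments noted per molecule make each zwitterion exactly
neutral.  All solutes are rigid bodies during sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_MASS

__all__ = ["SiteParameters", "MoleculeSpec", "embedded_parameters",
           "SPCE_O_CHARGE", "SPCE_H_CHARGE", "WATER_FF_O_CHARGE_SPC"]

SPCE_O_CHARGE = -0.8476
SPCE_H_CHARGE = +0.4238
SPCE_SIGMA_O = 3.166      # Å
SPCE_EPSILON_O = 0.650    # kJ/mol
SPCE_ROH = 1.0            # Å
SPCE_HOH_DEG = 109.47

#: SPC (not SPC/E) water oxygen charge, kept for comparison against
#: ESP-fitted charges of quantum waters.
WATER_FF_O_CHARGE_SPC = -0.834


@dataclass(frozen=True)
class SiteParameters:
    """Per-site nonbonded parameters: LJ sigma (Å), epsilon (kJ/mol), charge (e)."""
    name: str
    element: str
    sigma: float
    epsilon: float
    charge: float


@dataclass(frozen=True)
class MoleculeSpec:
    """Rigid molecule: site parameters + fixed internal geometry (Å)."""
    name: str
    sites: tuple[SiteParameters, ...]
    coords: np.ndarray               # (n_sites, 3), molecule frame
    net_charge: float = 0.0
    # indices of the two carboxylate oxygens (positron expansion centers)
    carboxylate_oxygens: tuple[int, ...] = ()
    carboxylate_carbon: int | None = None
    hbond_donors: tuple[tuple[int, int], ...] = field(default_factory=tuple)   # (heavy, H)
    hbond_acceptors: tuple[int, ...] = field(default_factory=tuple)

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([s.sigma for s in self.sites])

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([s.epsilon for s in self.sites])

    @property
    def mass(self) -> float:
        return float(sum(ATOMIC_MASS[s.element] for s in self.sites))


def _water_spec() -> MoleculeSpec:
    half = math.radians(SPCE_HOH_DEG) / 2.0
    o = np.zeros(3)
    h1 = SPCE_ROH * np.array([math.sin(half), math.cos(half), 0.0])
    h2 = SPCE_ROH * np.array([-math.sin(half), math.cos(half), 0.0])
    sites = (
        SiteParameters("OW", "O", SPCE_SIGMA_O, SPCE_EPSILON_O, SPCE_O_CHARGE),
        SiteParameters("HW1", "H", 0.0, 0.0, SPCE_H_CHARGE),
        SiteParameters("HW2", "H", 0.0, 0.0, SPCE_H_CHARGE),
    )
    return MoleculeSpec(
        name="water", sites=sites, coords=np.array([o, h1, h2]),
        hbond_donors=((0, 1), (0, 2)), hbond_acceptors=(0,),
    )


# OPLS-AA-style LJ parameters by atom class (sigma Å, epsilon kJ/mol)
_LJ = {
    "N3": (3.25, 0.71128),    # ammonium N
    "CT": (3.50, 0.276144),   # aliphatic C
    "C": (3.75, 0.439320),    # carboxylate C
    "O2": (2.96, 0.878640),   # carboxylate O
    "HC": (2.50, 0.125520),   # H on aliphatic C
    "H3": (0.0, 0.0),         # H on N
}


def _site(name, element, cls, q):
    s, e = _LJ[cls]
    return SiteParameters(name, element, s, e, q)


# MMFF94-optimized stand-in geometries (frozen; see module docstring)
_GLYCINE_ATOMS = [
    ("N", -1.1420, 0.0348, 0.0426),
    ("C", 0.2167, -0.5806, -0.2151),
    ("C", 1.3136, 0.4539, 0.1291),
    ("O", 0.7616, 1.5317, 0.5324),
    ("O", 2.5010, 0.1067, -0.0274),
    ("H", -1.6508, -0.3988, 0.8118),
    ("H", -1.6933, 0.1831, -0.8015),
    ("H", -0.8444, 0.9897, 0.3792),
    ("H", 0.2465, -0.8547, -1.2725),
    ("H", 0.2911, -1.4656, 0.4214),
]

_ALANINE_ATOMS = [
    ("N", 0.7372, 1.0386, -0.4753),
    ("C", -0.0134, -0.2748, -0.3320),
    ("C", -1.4046, 0.0135, 0.1890),   # CB (methyl)
    ("C", 0.8209, -1.2179, 0.5833),   # carboxylate C
    ("O", 1.9838, -0.7144, 0.7436),
    ("O", 0.2732, -2.2504, 1.0183),
    ("H", 0.4535, 1.7348, 0.2157),
    ("H", 1.6936, 0.7331, -0.1550),
    ("H", 0.8059, 1.3945, -1.4264),
    ("H", -0.0471, -0.7078, -1.3372),
    ("H", -1.9252, 0.7343, -0.4501),
    ("H", -1.3729, 0.4184, 1.2066),
    ("H", -2.0050, -0.9019, 0.2196),
]

_PROLINE_ATOMS = [
    ("O", 1.6919, 1.0142, -1.3206),
    ("C", 1.9886, 0.2172, -0.3692),   # carboxylate C
    ("O", 2.9580, -0.5428, -0.1661),
    ("C", 0.8634, 0.2533, 0.7069),    # CA
    ("C", 0.1522, -1.0804, 0.8692),   # CB
    ("C", -1.0004, -1.0055, -0.1200), # CG
    ("C", -1.4893, 0.4215, 0.0155),   # CD
    ("N", -0.2593, 1.2046, 0.2417),
    ("H", 1.2496, 0.6477, 1.6516),
    ("H", 0.7930, -1.9459, 0.6759),
    ("H", -0.2391, -1.1725, 1.8897),
    ("H", -0.6404, -1.1905, -1.1391),
    ("H", -1.7859, -1.7343, 0.0994),
    ("H", -1.9957, 0.8026, -0.8746),
    ("H", -2.1197, 0.5538, 0.9001),
    ("H", -0.3276, 2.0500, 0.8108),
    ("H", 0.1608, 1.5070, -0.6782),
]


def _glycine_spec() -> MoleculeSpec:
    # charge classes: N -0.30, CA +0.09 (adjusted for neutrality),
    # C +0.70, O -0.80, HN +0.33, HA +0.06
    classes = ["N3", "CT", "C", "O2", "O2", "H3", "H3", "H3", "HC", "HC"]
    charges = [-0.30, 0.09, 0.70, -0.80, -0.80, 0.33, 0.33, 0.33, 0.06, 0.06]
    return _build_solute("glycine", _GLYCINE_ATOMS, classes, charges,
                         coo_oxygens=(3, 4), coo_carbon=2,
                         donors=((0, 5), (0, 6), (0, 7)), acceptors=(3, 4))


def _alanine_spec() -> MoleculeSpec:
    classes = ["N3", "CT", "CT", "C", "O2", "O2",
               "H3", "H3", "H3", "HC", "HC", "HC", "HC"]
    charges = [-0.30, 0.15, -0.18, 0.70, -0.80, -0.80,
               0.33, 0.33, 0.33, 0.06, 0.06, 0.06, 0.06]
    return _build_solute("alanine", _ALANINE_ATOMS, classes, charges,
                         coo_oxygens=(4, 5), coo_carbon=3,
                         donors=((0, 6), (0, 7), (0, 8)), acceptors=(4, 5))


def _proline_spec() -> MoleculeSpec:
    classes = ["O2", "C", "O2", "CT", "CT", "CT", "CT", "N3",
               "HC", "HC", "HC", "HC", "HC", "HC", "HC", "H3", "H3"]
    charges = [-0.80, 0.70, -0.80, 0.14, -0.12, -0.12, 0.12, -0.20,
               0.06, 0.06, 0.06, 0.06, 0.06, 0.06, 0.06, 0.33, 0.33]
    return _build_solute("proline", _PROLINE_ATOMS, classes, charges,
                         coo_oxygens=(0, 2), coo_carbon=1,
                         donors=((7, 15), (7, 16)), acceptors=(0, 2))


def _build_solute(name, atoms, classes, charges, coo_oxygens, coo_carbon,
                  donors, acceptors) -> MoleculeSpec:
    assert len(atoms) == len(classes) == len(charges)
    total = sum(charges)
    if abs(total) > 1e-9:
        raise ValueError(f"{name}: site charges sum to {total}, expected 0")
    sites = tuple(
        _site(f"{el}{i}", el, cls, q)
        for i, ((el, *_), cls, q) in enumerate(zip(atoms, classes, charges))
    )
    coords = np.array([[x, y, z] for (_, x, y, z) in atoms])
    coords = coords - coords.mean(axis=0)      # center on centroid
    return MoleculeSpec(name=name, sites=sites, coords=coords,
                        carboxylate_oxygens=coo_oxygens,
                        carboxylate_carbon=coo_carbon,
                        hbond_donors=donors, hbond_acceptors=acceptors)


_REGISTRY = {
    "water": _water_spec,
    "glycine": _glycine_spec,
    "alanine": _alanine_spec,
    "proline": _proline_spec,
}


def embedded_parameters(name: str) -> MoleculeSpec:
    """Return the embedded rigid-body parameter set for a molecule.

    Parameters
    ----------
    name : one of ``water``, ``glycine``, ``alanine``, ``proline``
        (case-insensitive; ``water/SPC/E`` is accepted as an alias).
    """
    key = name.lower()
    if key.startswith("water"):
        key = "water"
    if key not in _REGISTRY:
        raise KeyError(f"unknown molecule {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[key]()
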