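"""Gaussian basis sets: shells, minimal built-in sets, Gaussian94 parsing,
and even-tempered generation for the positron.

Angular momenta up to d are supported, with Cartesian d components (6d).
Every Cartesian component is individually normalized to unit self-overlap.
The built-in minimal electron basis ("posaqua-min") is a 3-Gaussian
expansion of Slater orbitals fitted in-repo (the 1s expansion reproduces
the classic STO-3G coefficients to 7 digits), with standard Slater
exponents per element; it is a stand-in adequate for the desk-scale
fixtures, not a replacement for production Pople sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import BOHR_PER_ANGSTROM

__all__ = ["GaussianShell", "BasisSet", "build_even_tempered",
           "parse_gaussian94", "minimal_basis_shells", "CARTESIAN_COMPONENTS"]

L_OF = {"s": 0, "p": 1, "d": 2}
SYM_OF = {v: k for k, v in L_OF.items()}

CARTESIAN_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def _contracted_self_overlap(l, exps, coefs):
    """Self-overlap of a contracted (l,0,0) component with per-primitive
    component norms folded in (component-independent, see module doc)."""
    s = 0.0
    for a, ca in zip(exps, coefs):
        for b, cb in zip(exps, coefs):
            p = a + b
            na = (2 * a / np.pi) ** 0.75 * (4 * a) ** (l / 2)
            nb = (2 * b / np.pi) ** 0.75 * (4 * b) ** (l / 2)
            s += ca * cb * na * nb * (np.pi / p) ** 1.5 / (2 * p) ** l
    return s


@dataclass
class GaussianShell:
    """A contracted Cartesian Gaussian shell.

    center is stored in bohr; exponents in bohr^-2.  Contraction
    coefficients are renormalized at construction so that each Cartesian
    component has unit self-overlap.
    """
    l: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.exps.size == 0 or np.any(self.exps <= 0):
            raise ValueError("shell needs >= 1 primitive with positive exponent")
        norm = _contracted_self_overlap(self.l, self.exps, self.coefs)
        self.coefs = self.coefs / np.sqrt(norm)

    @property
    def n_components(self) -> int:
        return len(CARTESIAN_COMPONENTS[self.l])


@dataclass
class BasisSet:
    """An ordered list of shells with a flat Cartesian AO index."""
    shells: list[GaussianShell] = field(default_factory=list)

    @property
    def n_functions(self) -> int:
        return sum(s.n_components for s in self.shells)

    def offsets(self) -> list[int]:
        out, pos = [], 0
        for s in self.shells:
            out.append(pos)
            pos += s.n_components
        return out

    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.shells])

    def __add__(self, other: "BasisSet") -> "BasisSet":
        return BasisSet(shells=list(self.shells) + list(other.shells))

    def __len__(self):
        return len(self.shells)


def build_even_tempered(alpha0: float, beta: float, n: int,
                        centers, shells: str = "s") -> BasisSet:
    """Even-tempered basis: exponents {alpha0 * beta^k, k=0..n-1}
    replicated on each center and each angular momentum in ``shells``
    (e.g. "spd").  Centers in bohr.
    """
    if alpha0 <= 0 or beta <= 1 or n < 1:
        raise ValueError("need alpha0 > 0, beta > 1, n >= 1")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    basis = BasisSet()
    for c in centers:
        for sym in shells:
            l = L_OF[sym]
            for k in range(n):
                basis.shells.append(GaussianShell(
                    l=l, center=c, exps=np.array([alpha0 * beta**k]),
                    coefs=np.array([1.0])))
    return basis


# 3-Gaussian expansions of Slater orbitals at zeta=1, fitted in-repo
# (exponent, coefficient); scale exponents by zeta^2 for an element.
_SLATER_3G = {
    "1s": [(2.22766073, 0.15432895), (0.4057712, 0.53532813),
           (0.10981752, 0.44463457)],
    "2s": [(1.03477, -0.08848135), (0.19860573, 0.48685766),
           (0.06820524, 0.60457075)],
    "2p": [(0.91923809, 0.16239483), (0.23591946, 0.56617089),
           (0.08009806, 0.4223072)],
}

# standard Slater exponents (zeta) per element and sub-shell
_SLATER_ZETA = {
    "H": {"1s": 1.24},
    "Li": {"1s": 2.69, "2s": 0.80, "2p": 0.80},
    "C": {"1s": 5.67, "2s": 1.72, "2p": 1.72},
    "N": {"1s": 6.67, "2s": 1.95, "2p": 1.95},
    "O": {"1s": 7.66, "2s": 2.25, "2p": 2.25},
}


def minimal_basis_shells(element: str, center_bohr) -> list[GaussianShell]:
    """Minimal ("posaqua-min") shells for one atom, center in bohr."""
    if element not in _SLATER_ZETA:
        raise KeyError(f"no minimal basis for element {element!r}")
    out = []
    for sub, zeta in _SLATER_ZETA[element].items():
        l = L_OF[sub[1]]
        prim = _SLATER_3G[sub]
        exps = np.array([a * zeta**2 for a, _ in prim])
        coefs = np.array([c for _, c in prim])
        out.append(GaussianShell(l=l, center=np.asarray(center_bohr, float),
                                 exps=exps, coefs=coefs))
    return out


def parse_gaussian94(text: str) -> dict[str, list[tuple[str, np.ndarray, np.ndarray]]]:
    """Parse a Gaussian94-format basis file into
    {element: [(shell_symbol, exponents, coefficient_columns), ...]}.

    SP shells are split into separate S and P entries.
    """
    blocks = {}
    lines = [ln.split("!")[0].rstrip() for ln in text.splitlines()]
    i = 0
    # skip leading blank/separator lines
    while i < len(lines) and (not lines[i].strip() or lines[i].strip() == "****"):
        i += 1
    while i < len(lines):
        head = lines[i].split()
        if not head:
            i += 1
            continue
        element = head[0].capitalize()
        i += 1
        shells = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "****":
            sym, nprim = lines[i].split()[:2]
            nprim = int(nprim)
            rows = []
            for k in range(1, nprim + 1):
                rows.append([float(x.replace("D", "E").replace("d", "e"))
                             for x in lines[i + k].split()])
            rows = np.array(rows)
            if sym.upper() == "SP":
                shells.append(("s", rows[:, 0], rows[:, 1]))
                shells.append(("p", rows[:, 0], rows[:, 2]))
            else:
                shells.append((sym.lower(), rows[:, 0], rows[:, 1]))
            i += nprim + 1
        blocks[element] = shells
        while i < len(lines) and (not lines[i].strip()
                                  or lines[i].strip() == "****"):
            i += 1
    return blocks


def basis_from_gaussian94(text: str, atoms) -> BasisSet:
    """Build a BasisSet for ``atoms`` = [(element, xyz_angstrom), ...]."""
    table = parse_gaussian94(text)
    basis = BasisSet()
    for element, xyz in atoms:
        if element not in table:
            raise KeyError(f"basis file lacks element {element!r}")
        for sym, exps, coefs in table[element]:
            basis.shells.append(GaussianShell(
                l=L_OF[sym], center=np.asarray(xyz, float) * BOHR_PER_ANGSTROM,
                exps=exps, coefs=coefs))
    return basis
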