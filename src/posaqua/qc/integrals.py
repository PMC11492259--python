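"""Assembly of integral matrices/tensors over shells, and the IntegralStore.

Sign conventions: ``attraction_matrix`` returns A[mu,nu] = sum_k q_k
(mu|1/|r-C_k||nu) for the *signed* source charges q_k.  The one-body
Hamiltonians are then h_e = T - A (electrons, charge -1) and h_p = T + A
(positron, charge +1).  The electron-positron two-body tensor is stored as
repulsion-type (mu nu|pq); its contribution to the energy enters with a
minus sign (opposite charges attract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _md
from .basis import CARTESIAN_COMPONENTS, BasisSet

__all__ = ["IntegralStore", "compute_integrals", "overlap_matrix",
           "kinetic_matrix", "attraction_matrix", "dipole_matrices",
           "eri_tensor", "eri_mixed", "canonical_orthogonalizer"]

_COMP = {l: np.array(CARTESIAN_COMPONENTS[l], dtype=np.int64)
         for l in (0, 1, 2)}


def _shell_args(shell):
    return (shell.l, shell.center, shell.exps, shell.coefs, _COMP[shell.l])


def _pairwise(basis_a: BasisSet, basis_b: BasisSet, block_fn, nout=1):
    na, nb = basis_a.n_functions, basis_b.n_functions
    off_a, off_b = basis_a.offsets(), basis_b.offsets()
    same = basis_a is basis_b
    out = np.zeros((nout, na, nb)) if nout > 1 else np.zeros((na, nb))
    for i, sa in enumerate(basis_a.shells):
        la, A, ea, ca_, compa = _shell_args(sa)
        j0 = i if same else 0
        for j in range(j0, len(basis_b.shells)):
            sb = basis_b.shells[j]
            lb, B, eb, cb_, compb = _shell_args(sb)
            blk = block_fn(la, lb, A, B, ea, ca_, eb, cb_, compa, compb)
            ia, jb = off_a[i], off_b[j]
            if nout > 1:
                out[:, ia:ia + blk.shape[1], jb:jb + blk.shape[2]] = blk
                if same and i != j:
                    out[:, jb:jb + blk.shape[2], ia:ia + blk.shape[1]] = \
                        np.transpose(blk, (0, 2, 1))
            else:
                out[ia:ia + blk.shape[0], jb:jb + blk.shape[1]] = blk
                if same and i != j:
                    out[jb:jb + blk.shape[1], ia:ia + blk.shape[0]] = blk.T
    return out


def overlap_matrix(basis: BasisSet) -> np.ndarray:
    return _pairwise(basis, basis, _md.overlap_block)


def kinetic_matrix(basis: BasisSet) -> np.ndarray:
    return _pairwise(basis, basis, _md.kinetic_block)


def dipole_matrices(basis: BasisSet) -> np.ndarray:
    """(3, n, n) first-moment integrals about the origin (bohr)."""
    return _pairwise(basis, basis, _md.moment_block, nout=3)


def attraction_matrix(basis: BasisSet, centers: np.ndarray,
                      charges: np.ndarray) -> np.ndarray:
    """A[mu,nu] = sum_k q_k (mu| 1/|r-C_k| |nu), centers in bohr."""
    centers = np.atleast_2d(np.asarray(centers, float))
    charges = np.asarray(charges, float)
    if centers.shape[0] == 0:
        return np.zeros((basis.n_functions, basis.n_functions))

    def fn(la, lb, A, B, ea, ca_, eb, cb_, compa, compb):
        return _md.attraction_block(la, lb, A, B, ea, ca_, eb, cb_,
                                    compa, compb, centers, charges)
    return _pairwise(basis, basis, fn)


def eri_tensor(basis: BasisSet) -> np.ndarray:
    """Full (mu nu|la si) repulsion tensor with 8-fold symmetry filling."""
    n = basis.n_functions
    off = basis.offsets()
    shells = basis.shells
    out = np.zeros((n, n, n, n))
    ns = len(shells)
    for i in range(ns):
        for j in range(i, ns):
            for k in range(ns):
                for l in range(k, ns):
                    if k * ns + l < i * ns + j:
                        continue
                    blk = _md.eri_block(
                        *(s.l for s in (shells[i], shells[j], shells[k],
                                        shells[l])),
                        shells[i].center, shells[j].center,
                        shells[k].center, shells[l].center,
                        shells[i].exps, shells[i].coefs,
                        shells[j].exps, shells[j].coefs,
                        shells[k].exps, shells[k].coefs,
                        shells[l].exps, shells[l].coefs,
                        _COMP[shells[i].l], _COMP[shells[j].l],
                        _COMP[shells[k].l], _COMP[shells[l].l])
                    oi, oj, ok, ol = off[i], off[j], off[k], off[l]
                    di, dj, dk, dl = blk.shape
                    out[oi:oi+di, oj:oj+dj, ok:ok+dk, ol:ol+dl] = blk
                    out[oj:oj+dj, oi:oi+di, ok:ok+dk, ol:ol+dl] = \
                        blk.transpose(1, 0, 2, 3)
                    out[oi:oi+di, oj:oj+dj, ol:ol+dl, ok:ok+dk] = \
                        blk.transpose(0, 1, 3, 2)
                    out[oj:oj+dj, oi:oi+di, ol:ol+dl, ok:ok+dk] = \
                        blk.transpose(1, 0, 3, 2)
                    out[ok:ok+dk, ol:ol+dl, oi:oi+di, oj:oj+dj] = \
                        blk.transpose(2, 3, 0, 1)
                    out[ol:ol+dl, ok:ok+dk, oi:oi+di, oj:oj+dj] = \
                        blk.transpose(3, 2, 0, 1)
                    out[ok:ok+dk, ol:ol+dl, oj:oj+dj, oi:oi+di] = \
                        blk.transpose(2, 3, 1, 0)
                    out[ol:ol+dl, ok:ok+dk, oj:oj+dj, oi:oi+di] = \
                        blk.transpose(3, 2, 1, 0)
    return out


def eri_mixed(basis_a: BasisSet, basis_b: BasisSet) -> np.ndarray:
    """(mu nu | p q) repulsion-type tensor between two different bases
    (bra pair in basis_a, ket pair in basis_b)."""
    na, nb = basis_a.n_functions, basis_b.n_functions
    off_a, off_b = basis_a.offsets(), basis_b.offsets()
    sa, sb = basis_a.shells, basis_b.shells
    out = np.zeros((na, na, nb, nb))
    for i in range(len(sa)):
        for j in range(i, len(sa)):
            for k in range(len(sb)):
                for l in range(k, len(sb)):
                    blk = _md.eri_block(
                        sa[i].l, sa[j].l, sb[k].l, sb[l].l,
                        sa[i].center, sa[j].center, sb[k].center, sb[l].center,
                        sa[i].exps, sa[i].coefs, sa[j].exps, sa[j].coefs,
                        sb[k].exps, sb[k].coefs, sb[l].exps, sb[l].coefs,
                        _COMP[sa[i].l], _COMP[sa[j].l],
                        _COMP[sb[k].l], _COMP[sb[l].l])
                    oi, oj, ok, ol = off_a[i], off_a[j], off_b[k], off_b[l]
                    di, dj, dk, dl = blk.shape
                    out[oi:oi+di, oj:oj+dj, ok:ok+dk, ol:ol+dl] = blk
                    out[oj:oj+dj, oi:oi+di, ok:ok+dk, ol:ol+dl] = \
                        blk.transpose(1, 0, 2, 3)
                    out[oi:oi+di, oj:oj+dj, ol:ol+dl, ok:ok+dk] = \
                        blk.transpose(0, 1, 3, 2)
                    out[oj:oj+dj, oi:oi+di, ol:ol+dl, ok:ok+dk] = \
                        blk.transpose(1, 0, 3, 2)
    return out


def canonical_orthogonalizer(S: np.ndarray, threshold: float = 1e-8):
    """X with X^T S X = 1, dropping near-dependent eigenvectors.

    Returns (X, n_dropped)."""
    w, V = np.linalg.eigh(S)
    keep = w > threshold
    X = V[:, keep] / np.sqrt(w[keep])
    return X, int((~keep).sum())


@dataclass
class IntegralStore:
    """All AO-basis integrals needed by the coupled SCF."""
    S_e: np.ndarray | None = None
    T_e: np.ndarray | None = None
    A_e: np.ndarray | None = None        # signed-charge attraction over e-basis
    S_p: np.ndarray | None = None
    T_p: np.ndarray | None = None
    A_p: np.ndarray | None = None
    eri_ee: np.ndarray | None = None
    eri_ep: np.ndarray | None = None     # (mu nu | p q), repulsion-type
    dip_e: np.ndarray | None = None
    dip_p: np.ndarray | None = None
    n_dropped_e: int = 0
    n_dropped_p: int = 0
    linear_dependence: bool = False


def compute_integrals(system) -> IntegralStore:
    """Compute the full integral store for a QuantumSystem."""
    store = IntegralStore()
    centers, charges = system.all_charges_bohr()
    if system.electron_basis is not None and system.n_electrons > 0:
        eb = system.electron_basis
        store.S_e = overlap_matrix(eb)
        store.T_e = kinetic_matrix(eb)
        store.A_e = attraction_matrix(eb, centers, charges)
        store.dip_e = dipole_matrices(eb)
        if system.n_electrons > 1:
            store.eri_ee = eri_tensor(eb)
        w = np.linalg.eigvalsh(store.S_e)
        if w.min() < 1e-8:
            store.linear_dependence = True
    if system.positron_basis is not None and system.n_positrons > 0:
        pb = system.positron_basis
        store.S_p = overlap_matrix(pb)
        store.T_p = kinetic_matrix(pb)
        store.A_p = attraction_matrix(pb, centers, charges)
        store.dip_p = dipole_matrices(pb)
        w = np.linalg.eigvalsh(store.S_p)
        if w.min() < 1e-8:
            store.linear_dependence = True
    if (store.S_e is not None and store.S_p is not None):
        store.eri_ep = eri_mixed(system.electron_basis, system.positron_basis)
    return store
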