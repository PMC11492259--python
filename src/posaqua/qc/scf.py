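"""Coupled two-component SCF: closed-shell electrons + one positron.

The electron Fock operator carries the usual Coulomb/exchange terms plus
the attraction to the positron density; the positron Fock operator (no
exchange: a single particle) carries the attraction to the electron
density.  Both sectors are converged simultaneously by Roothaan iteration
with DIIS acceleration and early-iteration damping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .integrals import IntegralStore, canonical_orthogonalizer, compute_integrals
from .system import QuantumSystem

__all__ = ["SCFOptions", "TwoComponentSCFResult", "scf_solve"]

log = logging.getLogger(__name__)


@dataclass
class SCFOptions:
    max_cycles: int = 200
    energy_tol: float = 1e-8          # hartree
    density_tol: float = 1e-6         # RMS
    diis_size: int = 8
    diis_start: int = 2
    damping: float = 0.3              # mixing of previous Fock, early cycles
    damping_until: int = 6
    lindep_threshold: float = 1e-8


@dataclass
class TwoComponentSCFResult:
    system: QuantumSystem
    energy: float                      # hartree, includes classical offset
    converged: bool
    n_iter: int
    e_mo_energies: np.ndarray | None   # ascending
    e_mo_coeffs: np.ndarray | None
    n_occ: int                         # occupied spatial electron orbitals
    electron_occupancy: float          # 2.0 closed shell, 1.0 single electron
    p_mo_energies: np.ndarray | None
    p_mo_coeffs: np.ndarray | None
    D_e: np.ndarray | None
    D_p: np.ndarray | None
    iteration_log: list = field(default_factory=list)

    @property
    def epsilon_somo(self) -> float:
        """Energy of the occupied (lowest) positron orbital, hartree."""
        if self.p_mo_energies is None:
            raise ValueError("no positron sector in this result")
        return float(self.p_mo_energies[0])


def _density(C, n_occ):
    Cocc = C[:, :n_occ]
    return Cocc @ Cocc.T


def _diis_extrapolate(focks, errors):
    n = len(focks)
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.dot(errors[i].ravel(), errors[j].ravel())
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return focks[-1]
    out = np.zeros_like(focks[-1])
    for ci, F in zip(c, focks):
        out += ci * F
    return out


def scf_solve(system: QuantumSystem,
              options: SCFOptions | None = None,
              integrals: IntegralStore | None = None) -> TwoComponentSCFResult:
    """Converge the coupled electron/positron SCF for ``system``."""
    opt = options or SCFOptions()
    ints = integrals if integrals is not None else compute_integrals(system)

    has_e = system.n_electrons > 0
    has_p = system.n_positrons > 0
    occ_e = system.n_electrons // 2 if system.n_electrons > 1 else 1
    f_occ = 2.0 if system.n_electrons > 1 else 1.0

    X_e = X_p = None
    h_e = h_p = None
    if has_e:
        h_e = ints.T_e - ints.A_e
        X_e, ndrop = canonical_orthogonalizer(ints.S_e, opt.lindep_threshold)
        ints.n_dropped_e = ndrop
        if ndrop:
            log.warning("electron basis: dropped %d near-dependent vectors",
                        ndrop)
        if X_e.shape[1] < occ_e:
            raise ValueError("electron basis too small for electron count")
    if has_p:
        h_p = ints.T_p + ints.A_p
        X_p, ndrop = canonical_orthogonalizer(ints.S_p, opt.lindep_threshold)
        ints.n_dropped_p = ndrop
        if ndrop:
            log.warning("positron basis: dropped %d near-dependent vectors",
                        ndrop)

    e_nuc = system.nuclear_repulsion()

    def solve_fock(F, X):
        Ft = X.T @ F @ X
        w, V = np.linalg.eigh(Ft)
        return w, X @ V

    # core-Hamiltonian guess
    D_e = D_p = None
    C_e = C_p = None
    eps_e = eps_p = None
    if has_e:
        eps_e, C_e = solve_fock(h_e, X_e)
        D_e = _density(C_e, occ_e)
    if has_p:
        eps_p, C_p = solve_fock(h_p, X_p)
        D_p = _density(C_p, 1)

    def energy_of(D_e, D_p, F_e, F_p):
        e = e_nuc
        if has_e:
            e += f_occ * np.sum(D_e * h_e)
            if ints.eri_ee is not None:
                J = np.einsum("mnls,ls->mn", ints.eri_ee, D_e)
                K = np.einsum("mlns,ls->mn", ints.eri_ee, D_e)
                e += np.sum(D_e * (2.0 * J - K)) if f_occ == 2.0 else 0.0
        if has_p:
            e += np.sum(D_p * h_p)
        if has_e and has_p and ints.eri_ep is not None:
            e -= f_occ * np.einsum("mnpq,mn,pq->", ints.eri_ep, D_e, D_p)
        return float(e)

    energy = 0.0
    focks_e, errs_e, focks_p, errs_p = [], [], [], []
    F_e_prev = F_p_prev = None
    history = []
    converged = False
    it = 0
    for it in range(1, opt.max_cycles + 1):
        F_e = F_p = None
        if has_e:
            F_e = h_e.copy()
            if ints.eri_ee is not None and f_occ == 2.0:
                J = np.einsum("mnls,ls->mn", ints.eri_ee, D_e)
                K = np.einsum("mlns,ls->mn", ints.eri_ee, D_e)
                F_e += 2.0 * J - K
            if has_p and ints.eri_ep is not None:
                F_e -= np.einsum("mnpq,pq->mn", ints.eri_ep, D_p)
        if has_p:
            F_p = h_p.copy()
            if has_e and ints.eri_ep is not None:
                F_p -= f_occ * np.einsum("mnpq,mn->pq", ints.eri_ep, D_e)

        e_new = energy_of(D_e, D_p, F_e, F_p)

        # DIIS / damping
        if has_e:
            err = F_e @ D_e @ ints.S_e - ints.S_e @ D_e @ F_e
            focks_e.append(F_e.copy())
            errs_e.append(err)
            if len(focks_e) > opt.diis_size:
                focks_e.pop(0)
                errs_e.pop(0)
        if has_p:
            errp = F_p @ D_p @ ints.S_p - ints.S_p @ D_p @ F_p
            focks_p.append(F_p.copy())
            errs_p.append(errp)
            if len(focks_p) > opt.diis_size:
                focks_p.pop(0)
                errs_p.pop(0)

        max_err = 0.0
        if has_e:
            max_err = max(max_err, float(np.abs(errs_e[-1]).max()))
        if has_p:
            max_err = max(max_err, float(np.abs(errs_p[-1]).max()))

        use_diis = it > opt.diis_start
        if has_e:
            F_eff = (_diis_extrapolate(focks_e, errs_e) if use_diis else F_e)
            if it <= opt.damping_until and F_e_prev is not None:
                F_eff = (1 - opt.damping) * F_eff + opt.damping * F_e_prev
            F_e_prev = F_eff
            eps_e, C_e = solve_fock(F_eff, X_e)
            D_e_new = _density(C_e, occ_e)
        if has_p:
            F_eff_p = (_diis_extrapolate(focks_p, errs_p) if use_diis else F_p)
            if it <= opt.damping_until and F_p_prev is not None:
                F_eff_p = (1 - opt.damping) * F_eff_p + opt.damping * F_p_prev
            F_p_prev = F_eff_p
            eps_p, C_p = solve_fock(F_eff_p, X_p)
            D_p_new = _density(C_p, 1)

        d_rms = 0.0
        if has_e:
            d_rms = max(d_rms, float(np.sqrt(np.mean((D_e_new - D_e) ** 2))))
            D_e = D_e_new
        if has_p:
            d_rms = max(d_rms, float(np.sqrt(np.mean((D_p_new - D_p) ** 2))))
            D_p = D_p_new

        dE = e_new - energy
        energy = e_new
        history.append({"iter": it, "energy": e_new, "dE": dE,
                        "d_rms": d_rms, "diis_err": max_err})
        if it > 1 and abs(dE) < opt.energy_tol and d_rms < opt.density_tol:
            converged = True
            break

    if not converged:
        log.warning("SCF did not converge in %d cycles (dE=%.2e)", it,
                    history[-1]["dE"] if history else np.nan)

    return TwoComponentSCFResult(
        system=system, energy=energy, converged=converged, n_iter=it,
        e_mo_energies=eps_e, e_mo_coeffs=C_e, n_occ=occ_e if has_e else 0,
        electron_occupancy=f_occ if has_e else 0.0,
        p_mo_energies=eps_p, p_mo_coeffs=C_p,
        D_e=D_e, D_p=D_p, iteration_log=history)
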