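"""Positron binding energies (dSCF, Koopmans, P2) and dipole moments.

Three estimates of the positron binding energy (PBE), all in meV:

* PBE_HF: difference of separately converged SCF energies of the parent
  molecule X and the positronic complex Xe+ (vertical attachment).
* PBE_KT: the Koopmans estimate, minus the energy of the positron's
  singly occupied orbital (SOMO).
* PBE_P2: the quasi-particle pole of the second-order positron
  self-energy, omega = eps_SOMO + Sigma(omega), which adds electronic
  relaxation (reduces binding) and electron-positron pair-removal
  correlation (increases binding) on top of the Koopmans value.

A positive PBE means a bound state; unbound cases are reported as
PBE <= 0 rather than as errors (surface-state analysis needs them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import AU_TO_DEBYE, HARTREE_TO_MEV
from .qc.integrals import IntegralStore
from .qc.scf import TwoComponentSCFResult

__all__ = ["PBEReport", "P2Workspace", "pbe_delta_scf", "pbe_koopmans",
           "p2_self_energy", "pbe_p2_iterate", "dipole_moment"]

log = logging.getLogger(__name__)

DENOM_FLOOR = 1e-6  # hartree; smaller denominators are shift-regularized


@dataclass
class PBEReport:
    """Positron binding energies and the P2 decomposition (meV).

    The identity PBE_P2 = PBE_KT + relaxation + correlation holds by
    construction at the converged pole.
    """
    pbe_kt: float
    pbe_p2: float
    relaxation: float          # < 0 for bound solutes (reduces binding)
    correlation: float         # > 0 (pair removal, increases binding)
    omega: float               # converged pole, hartree
    n_iter: int
    converged: bool
    pbe_hf: float | None = None
    method: str = "newton"

    @property
    def bound(self) -> bool:
        return self.pbe_p2 > 0


def pbe_delta_scf(parent: TwoComponentSCFResult,
                  complex_: TwoComponentSCFResult) -> float:
    """PBE_HF = E(X) - E(Xe+) in meV; positive = bound."""
    if complex_.system.n_positrons != 1:
        raise ValueError("complex must contain one positron")
    if parent.system.n_positrons != 0:
        raise ValueError("parent must be purely electronic")
    if (parent.system.n_electrons != complex_.system.n_electrons
            or parent.system.coords.shape != complex_.system.coords.shape
            or not np.allclose(parent.system.coords, complex_.system.coords)):
        raise ValueError("parent and complex systems do not match")
    return (parent.energy - complex_.energy) * HARTREE_TO_MEV


def frozen_environment_complex(parent: TwoComponentSCFResult,
                               integrals: IntegralStore):
    """Positron attached to the *frozen* parent electron density.

    Diagonalizes the positron Fock operator built from the converged
    parent density without relaxing the electrons; returns
    (total_energy, eps_somo).  By construction
    E(X) - E_frozen(Xe+) = -eps_somo exactly (Koopmans equivalence).
    """
    from .qc.integrals import canonical_orthogonalizer
    if integrals.T_p is None:
        raise ValueError("no positron basis in the integral store")
    h_p = integrals.T_p + integrals.A_p
    F_p = h_p.copy()
    if parent.D_e is not None and integrals.eri_ep is not None:
        F_p -= parent.electron_occupancy * np.einsum(
            "mnpq,mn->pq", integrals.eri_ep, parent.D_e)
    X, _ = canonical_orthogonalizer(integrals.S_p)
    w, V = np.linalg.eigh(X.T @ F_p @ X)
    eps0 = float(w[0])
    return parent.energy + eps0, eps0


def pbe_koopmans(result: TwoComponentSCFResult) -> float:
    """PBE_KT = -eps_SOMO in meV (<= 0 flags an unbound Koopmans state)."""
    if result.system.n_positrons != 1:
        raise ValueError("no positron in this SCF result")
    pbe = -result.epsilon_somo * HARTREE_TO_MEV
    if pbe <= 0:
        log.info("Koopmans estimate unbound (eps_SOMO >= 0)")
    return pbe


@dataclass
class P2Workspace:
    """MO-basis quantities entering the second-order positron self-energy.

    v_pair[i, a, q] = (p q | i a): SOMO->virtual positron transition
    coupled to the electron excitation i->a (repulsion-type integral);
    v_relax[i, a] = (p p | i a): the SOMO density coupled to i->a.
    """
    eps_i: np.ndarray          # occupied electron orbital energies
    eps_a: np.ndarray          # virtual electron orbital energies
    eps_p: float               # positron SOMO energy
    eps_q: np.ndarray          # virtual positron orbital energies
    v_pair: np.ndarray         # (n_occ, n_vir, n_qvir)
    v_relax: np.ndarray        # (n_occ, n_vir)
    spin_factor: float = 2.0

    @classmethod
    def from_scf(cls, result: TwoComponentSCFResult,
                 integrals: IntegralStore) -> "P2Workspace":
        if integrals.eri_ep is None:
            raise ValueError("electron-positron integrals unavailable")
        n_occ = result.n_occ
        C_e = result.e_mo_coeffs
        C_p = result.p_mo_coeffs
        Ci = C_e[:, :n_occ]
        Ca = C_e[:, n_occ:]
        # (mu nu | p q) -> (i a | 0 k)
        half = np.einsum("mnpq,mi,na->iapq", integrals.eri_ep, Ci, Ca,
                         optimize=True)
        full = np.einsum("iapq,p,qk->iak", half, C_p[:, 0], C_p,
                         optimize=True)
        return cls(
            eps_i=result.e_mo_energies[:n_occ],
            eps_a=result.e_mo_energies[n_occ:],
            eps_p=float(result.p_mo_energies[0]),
            eps_q=result.p_mo_energies[1:],
            v_pair=full[:, :, 1:],
            v_relax=full[:, :, 0],
            spin_factor=result.electron_occupancy,
        )


def _safe_denominator(d: np.ndarray) -> np.ndarray:
    small = np.abs(d) < DENOM_FLOOR
    if np.any(small):
        log.warning("regularized %d near-vanishing P2 denominators",
                    int(small.sum()))
        d = np.where(small, np.sign(d) * DENOM_FLOOR + (d == 0) * DENOM_FLOOR,
                     d)
    return d


def p2_self_energy(workspace: P2Workspace, omega: float):
    """Second-order positron self-energy at trial energy ``omega``.

    Returns (sigma, relaxation_part, pair_removal_part, dsigma_domega),
    all in hartree.  The pair-removal class sums over occupied-electron x
    virtual-electron x virtual-positron triples; the relaxation class over
    electron particle-hole pairs coupled through the occupied positron
    orbital.
    """
    ws = workspace
    f = ws.spin_factor
    # pair removal: omega + eps_i - eps_a - eps_q
    d_pr = _safe_denominator(
        omega + ws.eps_i[:, None, None] - ws.eps_a[None, :, None]
        - ws.eps_q[None, None, :])
    v2_pr = ws.v_pair ** 2
    sigma_pr = f * np.sum(v2_pr / d_pr)
    dsig_pr = -f * np.sum(v2_pr / d_pr**2)
    # relaxation: omega + eps_a - eps_i - eps_p
    d_rx = _safe_denominator(
        omega + ws.eps_a[None, :] - ws.eps_i[:, None] - ws.eps_p)
    v2_rx = ws.v_relax ** 2
    sigma_rx = f * np.sum(v2_rx / d_rx)
    dsig_rx = -f * np.sum(v2_rx / d_rx**2)
    return (float(sigma_pr + sigma_rx), float(sigma_rx), float(sigma_pr),
            float(dsig_pr + dsig_rx))


def pbe_p2_iterate(workspace_or_result,
                   integrals: IntegralStore | None = None,
                   tol: float = 1e-8, max_iter: int = 100) -> PBEReport:
    """Solve omega = eps_SOMO + Sigma(omega) for the quasi-particle pole
    continuously connected to the SOMO (Newton from omega0 = eps_SOMO,
    bisection fallback on oscillation), and report the PBE decomposition.
    """
    if isinstance(workspace_or_result, P2Workspace):
        ws = workspace_or_result
    else:
        ws = P2Workspace.from_scf(workspace_or_result, integrals)

    eps = ws.eps_p
    omega = eps
    method = "newton"
    converged = False
    prev_steps = []
    for it in range(1, max_iter + 1):
        sigma, s_rx, s_pr, dsig = p2_self_energy(ws, omega)
        g = omega - eps - sigma
        if abs(g) < tol:
            converged = True
            break
        dg = 1.0 - dsig
        step = -g / dg if abs(dg) > 1e-12 else -g
        # oscillation guard: fall back to damped fixed point
        prev_steps.append(step)
        if len(prev_steps) >= 4 and abs(step) > 0.9 * abs(prev_steps[-3]) \
                and np.sign(step) != np.sign(prev_steps[-2]):
            method = "bisection"
            step = 0.5 * (eps + sigma - omega)
        omega = omega + step
    else:
        it = max_iter
    if not converged:
        log.warning("P2 pole iteration did not converge (residual %.2e)",
                    abs(g))

    sigma, s_rx, s_pr, _ = p2_self_energy(ws, omega)
    pbe_kt = -eps * HARTREE_TO_MEV
    relaxation = -s_rx * HARTREE_TO_MEV
    correlation = -s_pr * HARTREE_TO_MEV
    pbe_p2 = pbe_kt + relaxation + correlation
    return PBEReport(pbe_kt=pbe_kt, pbe_p2=pbe_p2, relaxation=relaxation,
                     correlation=correlation, omega=float(omega),
                     n_iter=it, converged=converged, method=method)


def dipole_moment(result: TwoComponentSCFResult,
                  integrals: IntegralStore):
    """Total dipole (nuclei + embedding + electrons - ... with species
    charge signs) about the origin.  Returns (magnitude_debye, vector_debye).

    Warns via the returned dict when the system is charged (the dipole is
    then origin-dependent; the origin used is the coordinate origin).
    """
    sys_ = result.system
    centers, charges = sys_.all_charges_bohr()
    mu = np.einsum("k,kx->x", charges, centers)
    if result.D_e is not None and integrals.dip_e is not None:
        mu -= result.electron_occupancy * np.einsum(
            "xmn,mn->x", integrals.dip_e, result.D_e)
    if result.D_p is not None and integrals.dip_p is not None:
        mu += np.einsum("xmn,mn->x", integrals.dip_p, result.D_p)
    vec = mu * AU_TO_DEBYE
    if abs(sys_.total_charge()) > 1e-8:
        log.warning("dipole of a charged system (q=%+.3f e) is "
                    "origin-dependent; origin = coordinate origin",
                    sys_.total_charge())
    return float(np.linalg.norm(vec)), vec
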