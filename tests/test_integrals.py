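"""Gaussian integral engine: closed forms, quadrature cross-checks,
rotation/translation invariance and particle-sign symmetry."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from posaqua.constants import ANGSTROM_PER_BOHR
from posaqua.qc import _md
from posaqua.qc.basis import BasisSet, GaussianShell, minimal_basis_shells
from posaqua.qc.grids import becke_grid, eval_basis
from posaqua.qc.integrals import (attraction_matrix, canonical_orthogonalizer,
                                  compute_integrals, eri_mixed, eri_tensor,
                                  kinetic_matrix, overlap_matrix)
from posaqua.qc.scf import scf_solve
from posaqua.qc.system import QuantumSystem


def _s(center, a):
    return GaussianShell(0, center, [a], [1.0])


def test_overlap_identical_functions_is_one():
    b = BasisSet([_s([0, 0, 0], 0.7), _s([0, 0, 0], 0.7)])
    S = overlap_matrix(b)
    assert S[0, 1] == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("R", [0.5, 1.0, 2.5])
@pytest.mark.parametrize("a,b", [(1.0, 1.0), (0.3, 1.7)])
def test_overlap_gaussian_product_theorem(R, a, b):
    """Normalized s-s overlap = exp(-ab/(a+b) R^2) by the Gaussian
    product theorem (the stated closed-form oracle)."""
    basis = BasisSet([_s([0, 0, 0], a), _s([0, 0, R], b)])
    S = overlap_matrix(basis)
    # unnormalized product integral / norms
    exact = ((4 * a * b / (a + b) ** 2) ** 0.75
             * math.exp(-a * b / (a + b) * R * R))
    assert S[0, 1] == pytest.approx(exact, abs=1e-12)


def test_ssss_eri_closed_form():
    """(ss|ss) between four unit-norm s Gaussians equals the closed-form
    two-electron expression with the Boys function."""
    za, zb = 0.8, 1.3
    R = 1.7
    A = np.zeros(3)
    B = np.array([0.0, 0.0, R])
    bra = BasisSet([_s(A, za)])
    ket = BasisSet([_s(B, zb)])
    got = eri_mixed(bra, ket)[0, 0, 0, 0]
    p, q = 2 * za, 2 * zb
    alpha = p * q / (p + q)
    T = alpha * R * R
    f0 = 0.5 * math.sqrt(math.pi / T) * math.erf(math.sqrt(T))
    norm_a = (2 * za / math.pi) ** 1.5      # product of two unit norms
    norm_b = (2 * zb / math.pi) ** 1.5
    exact = (2 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
             * f0 * norm_a * norm_b)
    assert got == pytest.approx(exact, rel=1e-12)


def test_attraction_matches_quadrature_for_p_and_d():
    """Point-charge attraction integrals over p/d shells agree with direct
    Becke-grid quadrature of chi_mu(r) chi_nu(r)/|r-C|."""
    shells = [GaussianShell(1, [0, 0, 0], [0.9], [1.0]),
              GaussianShell(2, [0.5, -0.2, 0.3], [0.7], [1.0])]
    basis = BasisSet(shells)
    C = np.array([[0.8, 0.4, -0.6]])
    q = np.array([1.0])
    A = attraction_matrix(basis, C, q)
    pts, w = becke_grid(np.array([[0, 0, 0], C[0] * ANGSTROM_PER_BOHR]),
                        ["O", "H"], n_radial=90, n_theta=24)
    chi = eval_basis(basis, pts)
    rinv = 1.0 / np.linalg.norm(pts - C[0][None, :], axis=1)
    A_quad = np.einsum("g,gm,gn,g->mn", w, chi, chi, rinv)
    assert np.allclose(A, A_quad, atol=5e-6)


def test_eri_consistent_with_potential_quadrature():
    """(ab|cd) = int chi_a chi_b V_cd by quadrature, using the already
    validated attraction code for V_cd: an independent route through
    3D quadrature instead of the 6D Hermite algebra."""
    bra = BasisSet([GaussianShell(0, [0, 0, 0], [0.8], [1.0]),
                    GaussianShell(1, [0, 0, 1.2], [0.6], [1.0])])
    ket = BasisSet([GaussianShell(0, [0.5, 0, 0.5], [1.1], [1.0]),
                    GaussianShell(1, [0, 0.3, 0], [0.9], [1.0])])
    got = eri_mixed(bra, ket)

    centers = np.vstack([s.center for s in bra.shells]
                        + [s.center for s in ket.shells])
    pts, w = becke_grid(centers * ANGSTROM_PER_BOHR,
                        ["O"] * len(centers), n_radial=80, n_theta=21)
    chi_bra = eval_basis(bra, pts)
    # V_cd(r) at the grid points via per-point attraction (esp) kernels
    nb = ket.n_functions
    V = np.empty((len(pts), nb, nb))
    from posaqua.qc.basis import CARTESIAN_COMPONENTS
    comp = {l: np.array(CARTESIAN_COMPONENTS[l], dtype=np.int64)
            for l in (0, 1, 2)}
    off = ket.offsets()
    V[:] = 0.0
    for i, si in enumerate(ket.shells):
        for j, sj in enumerate(ket.shells):
            ni, nj = si.n_components, sj.n_components
            for a in range(ni):
                for b in range(nj):
                    Dblk = np.zeros((ni, nj))
                    Dblk[a, b] = 1.0
                    out = np.zeros(len(pts))
                    _md.esp_pair_block(si.l, sj.l, si.center, sj.center,
                                       si.exps, si.coefs, sj.exps, sj.coefs,
                                       comp[si.l], comp[sj.l], pts, Dblk, out)
                    V[:, off[i] + a, off[j] + b] += out
    quad = np.einsum("g,gm,gn,gpq->mnpq", w, chi_bra, chi_bra, V)
    assert np.allclose(got, quad, atol=2e-5)


def _water_system(coords):
    shells = []
    elements = ["O", "H", "H"]
    for el, xyz in zip(elements, coords):
        shells.extend(minimal_basis_shells(el, np.asarray(xyz)
                                           / ANGSTROM_PER_BOHR))
    return QuantumSystem("water", elements, np.asarray(coords),
                         n_electrons=10, electron_basis=BasisSet(shells))


WATER = np.array([[0.0, 0.0, 0.1173],
                  [0.0, 0.7572, -0.4692],
                  [0.0, -0.7572, -0.4692]])


def test_rhf_energy_rotation_invariant():
    """Total RHF energy must be invariant under rigid rotation: a strong
    consistency check on every p-block integral."""
    e0 = scf_solve(_water_system(WATER)).energy
    R = Rotation.from_euler("zyx", [33.0, -48.0, 112.0],
                            degrees=True).as_matrix()
    e1 = scf_solve(_water_system(WATER @ R.T)).energy
    assert e1 == pytest.approx(e0, abs=1e-9)


def test_rhf_energy_translation_invariant():
    e0 = scf_solve(_water_system(WATER)).energy
    e1 = scf_solve(_water_system(WATER + np.array([3.1, -2.2, 5.9]))).energy
    assert e1 == pytest.approx(e0, abs=1e-9)


def test_species_swap_negates_attraction():
    """Swapping particle species flips the sign of the one-body
    charge-attraction matrix; kinetic/overlap are unchanged."""
    coords = np.array([[0.0, 0.0, 0.0]])
    basis_def = lambda: BasisSet([_s([0, 0, 0], 0.5),
                                  GaussianShell(1, [0, 0, 0], [0.4], [1.0])])
    e_sys = QuantumSystem("e", ["H"], coords, n_electrons=1,
                          electron_basis=basis_def())
    p_sys = QuantumSystem("p", ["H"], coords, n_electrons=0, n_positrons=1,
                          positron_basis=basis_def())
    ints_e = compute_integrals(e_sys)
    ints_p = compute_integrals(p_sys)
    h_e = ints_e.T_e - ints_e.A_e
    h_p = ints_p.T_p + ints_p.A_p
    assert np.allclose(ints_e.T_e, ints_p.T_p, atol=1e-12)
    assert np.allclose(h_p - ints_p.T_p, -(h_e - ints_e.T_e), atol=1e-12)


def test_linear_dependence_flagged_and_dropped():
    b = BasisSet([_s([0, 0, 0], 0.5), _s([0, 0, 0], 0.5),
                  _s([0, 0, 0], 0.9)])
    S = overlap_matrix(b)
    X, dropped = canonical_orthogonalizer(S)
    assert dropped == 1
    assert np.allclose(X.T @ S @ X, np.eye(X.shape[1]), atol=1e-10)
    sys_ = QuantumSystem("dup", ["H"], np.zeros((1, 3)), n_electrons=1,
                         electron_basis=b)
    ints = compute_integrals(sys_)
    assert ints.linear_dependence
    res = scf_solve(sys_, integrals=ints)
    assert res.converged
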