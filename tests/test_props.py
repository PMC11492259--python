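"""Positron binding energies: dSCF/Koopmans/P2 and dipole moments."""

import numpy as np
import pytest

from posaqua.constants import EA_TO_DEBYE, HARTREE_TO_MEV
from posaqua.props import (P2Workspace, dipole_moment,
                           frozen_environment_complex, p2_self_energy,
                           pbe_delta_scf, pbe_koopmans, pbe_p2_iterate)
from posaqua.qc.integrals import compute_integrals
from posaqua.qc.scf import scf_solve
from posaqua.qc.system import QuantumSystem
from posaqua.synthetic import make_toy_quantum


@pytest.fixture(scope="module")
def lih():
    """Bound positronic complex shared by the module's tests."""
    sys_ = make_toy_quantum("lih+e+")
    ints = compute_integrals(sys_)
    parent = scf_solve(sys_.without_positron())
    complex_ = scf_solve(sys_, integrals=ints)
    assert parent.converged and complex_.converged
    return sys_, ints, parent, complex_


def test_identical_energies_give_zero_pbe(lih):
    _, _, parent, _ = lih
    assert pbe_delta_scf(parent, _fake_complex(parent)) == 0.0


def _fake_complex(parent):
    from dataclasses import replace
    sys_p = replace(parent.system, n_positrons=1)
    return replace(parent, system=sys_p)


def test_mismatched_systems_rejected(lih):
    _, _, parent, complex_ = lih
    with pytest.raises(ValueError):
        pbe_delta_scf(complex_, complex_)
    water = scf_solve(make_toy_quantum("water"))
    with pytest.raises(ValueError):
        pbe_delta_scf(water, complex_)


def test_koopmans_unit_conversion():
    """eps_SOMO = -0.02 hartree converts to 544.2 meV."""
    assert 0.02 * HARTREE_TO_MEV == pytest.approx(544.2277, abs=1e-3)


def test_koopmans_requires_positron():
    res = scf_solve(make_toy_quantum("water"))
    with pytest.raises(ValueError):
        pbe_koopmans(res)


def test_unbound_koopmans_reported_not_raised():
    res = scf_solve(make_toy_quantum("water+e+"))
    pbe = pbe_koopmans(res)
    assert pbe <= 0.0          # water alone does not bind at this level


def test_frozen_orbital_koopmans_equivalence(lih):
    """With electrons frozen at the parent solution, dSCF equals
    -eps_SOMO exactly."""
    sys_, ints, parent, _ = lih
    e_frozen, eps0 = frozen_environment_complex(parent, ints)
    d_scf = parent.energy - e_frozen
    assert d_scf == pytest.approx(-eps0, abs=1e-9)


def test_lih_is_bound_at_all_levels(lih):
    _, ints, parent, complex_ = lih
    pbe_hf = pbe_delta_scf(parent, complex_)
    pbe_kt = pbe_koopmans(complex_)
    report = pbe_p2_iterate(complex_, ints)
    assert pbe_hf > 0 and pbe_kt > 0 and report.pbe_p2 > 0
    # relaxed dSCF cannot exceed the frozen-environment Koopmans bound
    assert pbe_hf <= pbe_kt + 1e-6


def test_p2_sign_contract_on_bound_fixture(lih):
    """Electronic relaxation reduces the binding energy; e-p pair-removal
    correlation increases it."""
    _, ints, _, complex_ = lih
    report = pbe_p2_iterate(complex_, ints)
    assert report.converged
    assert report.relaxation < 0
    assert report.correlation > 0
    assert report.pbe_p2 == pytest.approx(
        report.pbe_kt + report.relaxation + report.correlation, abs=1e-9)


def test_p2_against_brute_force_diagram_sum():
    """model_p2: vectorized self-energy equals an explicit term-by-term
    double loop at several trial energies."""
    ws = make_toy_quantum("model_p2")
    # widen the model so the loops actually run over several terms
    rng = np.random.default_rng(7)
    ws = P2Workspace(
        eps_i=np.array([-1.2, -0.5]),
        eps_a=np.array([0.2, 0.7, 1.1]),
        eps_p=-0.03,
        eps_q=np.array([0.05, 0.4]),
        v_pair=rng.normal(scale=0.03, size=(2, 3, 2)),
        v_relax=rng.normal(scale=0.02, size=(2, 3)),
        spin_factor=2.0,
    )
    for omega in (-0.05, -0.02, 0.01):
        sig, rx, pr, dsig = p2_self_energy(ws, omega)
        rx_ref = pr_ref = 0.0
        for i, ei in enumerate(ws.eps_i):
            for a, ea in enumerate(ws.eps_a):
                rx_ref += (2.0 * ws.v_relax[i, a] ** 2
                           / (omega + ea - ei - ws.eps_p))
                for q, eq in enumerate(ws.eps_q):
                    pr_ref += (2.0 * ws.v_pair[i, a, q] ** 2
                               / (omega + ei - ea - eq))
        assert rx == pytest.approx(rx_ref, abs=1e-10)
        assert pr == pytest.approx(pr_ref, abs=1e-10)
        assert sig == pytest.approx(rx_ref + pr_ref, abs=1e-10)


def test_p2_pole_is_exact_eigenvalue_of_arrowhead_model():
    """For the model fixture the pole equation is exactly the eigenvalue
    problem of an arrowhead matrix; the converged quasi-particle pole must
    coincide with one of its eigenvalues and lie between the exact lowest
    pole and eps_SOMO."""
    ws = make_toy_quantum("model_p2")
    report = pbe_p2_iterate(ws)
    assert report.converged
    # build the arrowhead: diagonal couplings d_k with amplitudes v_k
    d, v = [], []
    f = np.sqrt(ws.spin_factor)
    for i, ei in enumerate(ws.eps_i):
        for a, ea in enumerate(ws.eps_a):
            d.append(ws.eps_p + ei - ea)          # relaxation channel
            v.append(f * ws.v_relax[i, a])
            for q, eq in enumerate(ws.eps_q):
                d.append(ea + eq - ei)            # pair-removal channel
                v.append(f * ws.v_pair[i, a, q])
    n = len(d) + 1
    H = np.zeros((n, n))
    H[0, 0] = ws.eps_p
    H[0, 1:] = v
    H[1:, 0] = v
    H[np.arange(1, n), np.arange(1, n)] = d
    eig = np.linalg.eigvalsh(H)
    assert np.min(np.abs(eig - report.omega)) < 1e-8
    assert eig.min() - 1e-12 <= report.omega <= ws.eps_p + 1e-12


def test_p2_zero_coupling_reduces_to_koopmans():
    ws = make_toy_quantum("model_p2")
    ws.v_pair = np.zeros_like(ws.v_pair)
    ws.v_relax = np.zeros_like(ws.v_relax)
    report = pbe_p2_iterate(ws)
    assert report.pbe_p2 == pytest.approx(report.pbe_kt, abs=1e-9)
    assert report.omega == pytest.approx(ws.eps_p, abs=1e-12)


def test_p2_linear_model_closed_form():
    """A single very distant channel makes Sigma(omega) ~ a + b*omega near
    the pole; the iterated solution must match the algebraic fixed point
    (eps + a)/(1 - b) of the linearized model."""
    ws = P2Workspace(eps_i=np.array([-0.5]), eps_a=np.array([99.5]),
                     eps_p=-0.02, eps_q=np.array([900.0]),
                     v_pair=np.array([[[3.0]]]),
                     v_relax=np.array([[2.0]]), spin_factor=2.0)
    report = pbe_p2_iterate(ws)
    # linearize Sigma around omega=eps_p
    s0, *_ , ds0 = p2_self_energy(ws, ws.eps_p)
    a = s0 - ds0 * ws.eps_p
    b = ds0
    omega_lin = (ws.eps_p + a) / (1.0 - b)
    assert report.omega == pytest.approx(omega_lin, rel=1e-4)


def test_dipole_point_charges_and_symmetry():
    """+1/-1 e at 1 Å -> 4.8032 D; a centrosymmetric neutral pair -> 0."""
    sys_ = QuantumSystem("dipole", ["H", "H"],
                         np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                         n_electrons=0,
                         nuclear_charges=np.array([1.0, -1.0]))
    ints = compute_integrals(sys_)
    res = scf_solve(sys_, integrals=ints)
    mag, vec = dipole_moment(res, ints)
    assert mag == pytest.approx(EA_TO_DEBYE, abs=1e-9)
    assert mag == pytest.approx(4.8032, abs=1e-3)

    sym = QuantumSystem("sym", ["O", "O"],
                        np.array([[-1.0, 0, 0], [1.0, 0, 0]]),
                        n_electrons=0,
                        nuclear_charges=np.array([4.0, 4.0]))
    ints2 = compute_integrals(sym)
    res2 = scf_solve(sym, integrals=ints2)
    mag2, _ = dipole_moment(res2, ints2)
    assert mag2 == pytest.approx(0.0, abs=1e-12)


def test_lih_dipole_magnitude(lih):
    """The LiH-like fixture is strongly polar (several Debye), comfortably
    above empirical critical dipoles."""
    _, ints, parent, _ = lih
    mag, _ = dipole_moment(parent, ints)
    assert 3.0 < mag < 8.0
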