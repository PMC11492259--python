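"""Annihilation rates, enhancement factors, RPD, ESP charges, cube export."""

import math

import numpy as np
import pytest
import scipy.constants as sc

from posaqua.annihilation import (annihilation_report, core_valence_split,
                                  density_overlaps, enhancement_factors,
                                  esp_charges, export_volumetric, gamma_hf,
                                  radial_probability)
from posaqua.constants import (ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM,
                               annihilation_rate_constant_ns)
from posaqua.qc.basis import BasisSet, GaussianShell
from posaqua.qc.integrals import compute_integrals
from posaqua.qc.scf import scf_solve
from posaqua.qc.system import QuantumSystem
from posaqua.synthetic import make_toy_quantum


def _gaussian_pair_result(zeta_e, zeta_p, sep_bohr=0.0):
    """One 'electron' and one positron, each in a single normalized
    s-Gaussian orbital; SCF machinery is bypassed by construction."""
    eb = BasisSet([GaussianShell(0, [0, 0, 0], [zeta_e], [1.0])])
    pb = BasisSet([GaussianShell(0, [0, 0, sep_bohr], [zeta_p], [1.0])])
    sys_ = QuantumSystem("toy", ["H"], np.zeros((1, 3)), n_electrons=1,
                         n_positrons=1, electron_basis=eb, positron_basis=pb)
    from posaqua.qc.scf import TwoComponentSCFResult
    one = np.array([[1.0]])
    return TwoComponentSCFResult(
        system=sys_, energy=0.0, converged=True, n_iter=0,
        e_mo_energies=np.array([-0.5]), e_mo_coeffs=one, n_occ=1,
        electron_occupancy=1.0, p_mo_energies=np.array([-0.1]),
        p_mo_coeffs=one, D_e=one, D_p=one)


def _analytic_density_overlap(za, zb, R):
    """int |g_a|^2 |g_b|^2 with normalized s-Gaussians separated by R:
    (2 za / pi)^{3/2} (2 zb / pi)^{3/2} (pi/(2za+2zb))^{3/2}
    exp(-(2za)(2zb)/(2za+2zb) R^2)  (Gaussian product theorem)."""
    a, b = 2 * za, 2 * zb
    return ((2 * za / math.pi) ** 1.5 * (2 * zb / math.pi) ** 1.5
            * (math.pi / (a + b)) ** 1.5
            * math.exp(-a * b / (a + b) * R * R))


def test_identical_gaussian_overlap_closed_form():
    """Both densities the same normalized s-Gaussian: S = (zeta/pi)^{3/2}
    by direct integration of the 4-Gaussian product."""
    zeta = 0.8
    res = _gaussian_pair_result(zeta, zeta)
    s = density_overlaps(res, n_radial=60, n_theta=17)
    exact = (zeta / math.pi) ** 1.5
    assert exact == pytest.approx(_analytic_density_overlap(zeta, zeta, 0.0),
                                  rel=1e-12)
    assert s[0] == pytest.approx(exact, abs=1e-6 * exact)


@pytest.mark.parametrize("za,zb,R", [(0.5, 0.5, 1.0), (0.3, 1.2, 2.0),
                                     (1.0, 0.05, 0.0)])
def test_grid_overlap_matches_analytic(za, zb, R):
    res = _gaussian_pair_result(za, zb, R)
    s = density_overlaps(res, n_radial=80, n_theta=21,
                         check_convergence=False)
    exact = _analytic_density_overlap(za, zb, R)
    assert s[0] == pytest.approx(exact, rel=1e-6, abs=1e-12)


def test_disjoint_orbitals_vanishing_overlap():
    res = _gaussian_pair_result(1.5, 1.5, sep_bohr=14.0)
    s = density_overlaps(res, n_radial=70, n_theta=17,
                         check_convergence=False)
    assert s[0] < 1e-10


def test_rate_constant_rederived_from_codata():
    """pi r0^2 c in ns^-1 per a.u. density, against scipy.constants as an
    independent CODATA source: ~50.47, agreement to 0.1%."""
    r0 = sc.physical_constants["classical electron radius"][0]
    a0 = sc.physical_constants["Bohr radius"][0]
    ref = math.pi * r0**2 * sc.c / a0**3 * 1e-9
    got = annihilation_rate_constant_ns()
    assert got == pytest.approx(ref, rel=1e-3)
    assert got == pytest.approx(50.47, abs=0.05)


def test_gamma_hf_scaling():
    assert gamma_hf([0.0]) == 0.0
    got = gamma_hf([0.01], spin_degeneracy=1.0)
    assert got == pytest.approx(0.5047, abs=0.001)


def test_enhancement_factor_reference_point():
    """gamma(-1.31 Ha) = 2 + (0.834/1.31)^2.15 ~ 2.379."""
    g = enhancement_factors([-1.31])[0]
    assert g == pytest.approx(2.0 + (0.834 / 1.31) ** 2.15, abs=1e-12)
    assert g == pytest.approx(2.379, abs=2e-3)


def test_enhancement_deep_core_limit_and_errors():
    g = enhancement_factors([-1e6])[0]
    assert g == pytest.approx(1.0, abs=1e-2)
    # monotone decrease toward deep orbitals
    gs = enhancement_factors([-0.3, -1.0, -5.0, -20.0])
    assert np.all(np.diff(gs) < 0)
    with pytest.raises(ValueError):
        enhancement_factors([-0.5, 0.1])


def test_core_valence_split_limits():
    s = np.array([0.01, 0.02])
    eps = np.array([-1.0, -0.3])
    out = core_valence_split(s, eps)       # nothing below -2 Ha
    assert out["gamma_hf_core"] == 0.0
    assert out["n_core"] == 0
    out2 = core_valence_split(s, np.array([-20.0, -0.3]))
    assert out2["n_core"] == 1
    assert out2["gamma_hf_core"] <= out2["gamma_hf_core"] \
        + out2["gamma_hf_valence"]


@pytest.fixture(scope="module")
def lih_complex():
    sys_ = make_toy_quantum("lih+e+")
    res = scf_solve(sys_)
    assert res.converged
    return res


def test_enhanced_rate_dominates_hf(lih_complex):
    rep = annihilation_report(lih_complex, n_radial=50, n_theta=14,
                              check_convergence=False)
    assert rep.gamma_ef >= rep.gamma_hf
    assert np.all(rep.overlaps >= 0)
    assert np.all(rep.gamma_factors >= 1.0)
    assert rep.gamma_hf_core <= rep.gamma_hf
    assert rep.gamma_ef_core <= rep.gamma_ef


def test_rpd_single_gaussian_peak_position():
    """For an s-Gaussian orbital exp(-zeta r^2), r^2 |phi|^2 peaks at
    r = sqrt(1/(2 zeta))."""
    zeta = 0.5
    res = _gaussian_pair_result(1.0, zeta)
    rpd = radial_probability(res, 0, r_max_angstrom=6.0, n_r=600,
                             n_theta=16)
    exact_bohr = math.sqrt(1.0 / (2 * zeta))
    assert rpd.r_max == pytest.approx(exact_bohr * ANGSTROM_PER_BOHR,
                                      abs=0.01)
    norm = np.trapezoid(rpd.density, rpd.r)
    assert norm == pytest.approx(1.0, abs=1e-3)
    assert np.all(rpd.density >= 0)
    assert rpd.fwhm is not None and rpd.fwhm > 0


def test_rpd_invalid_origin(lih_complex):
    with pytest.raises(ValueError):
        radial_probability(lih_complex, 5)


def test_esp_single_point_charge_exactly_recovered():
    """ESP generated by one unit nuclear charge: the fit returns exactly
    that charge distribution."""
    sys_ = QuantumSystem("pc", ["O", "H"],
                         np.array([[0.0, 0, 0], [0, 0, 2.0]]),
                         n_electrons=0,
                         nuclear_charges=np.array([1.0, 0.0]))
    ints = compute_integrals(sys_)
    res = scf_solve(sys_, integrals=ints)
    q, info = esp_charges(res, spacing=0.5)
    assert q[0] == pytest.approx(1.0, abs=1e-6)
    assert q[1] == pytest.approx(0.0, abs=1e-6)


def test_esp_dipole_field_recovered():
    sys_ = QuantumSystem("dip", ["O", "O"],
                         np.array([[0.0, 0, 0], [0, 0, 2.5]]),
                         n_electrons=0,
                         nuclear_charges=np.array([0.62, -0.62]))
    ints = compute_integrals(sys_)
    res = scf_solve(sys_, integrals=ints)
    q, _ = esp_charges(res, spacing=0.5)
    assert q[0] == pytest.approx(0.62, abs=1e-4)
    assert q[1] == pytest.approx(-0.62, abs=1e-4)


def test_esp_water_oxygen_negative():
    res = scf_solve(make_toy_quantum("water"))
    q, _ = esp_charges(res, spacing=0.45)
    assert q[0] < -0.2            # oxygen clearly negative
    assert abs(q.sum()) < 1e-8    # constrained to neutrality


def test_cube_export_normalization_and_contact_consistency(tmp_path,
                                                           lih_complex):
    """Exported positron density integrates to ~1; the contact-density
    cube sums to the overlap total within the coarse-grid tolerance."""
    out = tmp_path / "pos.cube"
    info = export_volumetric(lih_complex, "positron_density", out,
                             spacing=0.9, margin=24.0)
    text = out.read_text().splitlines()
    n_at = int(text[2].split()[0])
    data = np.array([float(x) for ln in text[6 + n_at:] for x in ln.split()])
    total = data.sum() * info["voxel_volume_bohr3"]
    assert total == pytest.approx(1.0, abs=0.02)

    out2 = tmp_path / "contact.cube"
    info2 = export_volumetric(lih_complex, "contact_density", out2,
                              spacing=0.45, margin=8.0)
    data2 = np.array([float(x) for ln in
                      out2.read_text().splitlines()[6 + n_at:]
                      for x in ln.split()])
    total2 = data2.sum() * info2["voxel_volume_bohr3"]
    s = density_overlaps(lih_complex, n_radial=50, n_theta=14,
                         check_convergence=False)
    expected = lih_complex.electron_occupancy * s.sum()
    assert total2 == pytest.approx(expected, rel=0.05)
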