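"""Metropolis NpT engine: pair energies, sampling, autocorrelation."""

import math

import numpy as np
import pytest

from posaqua.constants import ATM_TO_KJMOL_A3, COULOMB_KJ_A, KB_KJMOL
from posaqua.forcefield import embedded_parameters
from posaqua.liquid import RigidMolecule
from posaqua.mc import (MCParams, configuration_energy,
                        energy_autocorrelation, pair_energy, run_npt,
                        select_uncorrelated)
from posaqua.synthetic import FixtureSpec, make_lattice_box


def _posed_water(position, rotation=None):
    spec = embedded_parameters("water")
    R = np.eye(3) if rotation is None else rotation
    return RigidMolecule(spec, spec.coords @ R.T + np.asarray(position))


def test_pair_energy_against_site_sum_oracle():
    """Two SPC/E waters in donor geometry (one O-H of the upper molecule
    aligned with the O...O axis): the kernel must equal an independently
    hand-summed 9-term Coulomb + 1-term LJ oracle."""
    from scipy.spatial.transform import Rotation
    spec0 = embedded_parameters("water")
    oh = spec0.coords[1] - spec0.coords[0]
    R, _ = Rotation.align_vectors([[0.0, -1.0, 0.0]], [oh])
    flip = np.diag([1.0, -1.0, -1.0])     # acceptor H's point away
    a = _posed_water([0.0, 0.0, 0.0], rotation=flip)
    b = _posed_water([0.0, 2.75, 0.0], rotation=R.as_matrix())
    got = pair_energy(a, b)

    spec = embedded_parameters("water")
    expected = 0.0
    for i in range(3):
        for j in range(3):
            r = np.linalg.norm(a.coords[i] - b.coords[j])
            expected += (COULOMB_KJ_A * spec.charges[i] * spec.charges[j]
                         / r)
    roo = np.linalg.norm(a.coords[0] - b.coords[0])
    sig, eps = spec.sigmas[0], spec.epsilons[0]
    expected += 4 * eps * ((sig / roo) ** 12 - (sig / roo) ** 6)
    assert got == pytest.approx(expected, abs=1e-10)
    # hydrogen-bonding geometry should be attractive
    assert got < -10.0
    # symmetry in the arguments
    assert pair_energy(b, a) == pytest.approx(got, abs=1e-10)


def test_pair_energy_beyond_cutoff_is_zero():
    a = _posed_water([0, 0, 0])
    b = _posed_water([0, 0, 8.0])
    assert pair_energy(a, b, box_edge=30.0, cutoff=6.0) == 0.0


def test_pair_energy_cutoff_exceeding_half_box_rejected():
    a = _posed_water([0, 0, 0])
    b = _posed_water([0, 0, 3.0])
    with pytest.raises(ValueError):
        pair_energy(a, b, box_edge=10.0, cutoff=6.0)


def test_ideal_gas_volume_matches_closed_form():
    """LJ and charges off: <V> must equal (N+1) kT / p."""
    cfg = make_lattice_box(FixtureSpec(seed=1, n_waters=64))
    p_atm = 1000.0
    params = MCParams(n_steps=300_000, n_equilibration=100_000,
                      pressure=p_atm, lj_on=False, coulomb_on=False,
                      tail_correction=False, cutoff=5.0, seed=4,
                      volume_amplitude=2000.0)
    traj = run_npt(cfg, params)
    v = np.array([s.box_edge ** 3 for s in traj.samples])
    v_ideal = (64 + 1) * KB_KJMOL * params.temperature \
        / (p_atm * ATM_TO_KJMOL_A3)
    assert v.mean() == pytest.approx(v_ideal, rel=0.03)


def test_high_temperature_acceptance_approaches_one():
    cfg = make_lattice_box(FixtureSpec(seed=2, n_waters=27))
    params = MCParams(n_steps=20_000, n_equilibration=0,
                      temperature=1e7, volume_move_interval=0,
                      max_translation=0.05, max_rotation=0.05, seed=1)
    traj = run_npt(cfg, params)
    acc = traj.acceptance["move"]
    assert acc["accepted"] / acc["attempted"] > 0.99


def test_energy_bookkeeping_incremental_vs_recomputed():
    """dU accumulated over many accepted moves equals a full recompute."""
    cfg = make_lattice_box(FixtureSpec(seed=3, n_waters=64,
                                       solute="glycine"))
    params = MCParams(n_steps=40_000, n_equilibration=10_000, seed=7,
                      sample_stride=40_000, cutoff=6.0)
    traj = run_npt(cfg, params)
    u_sampled = traj.samples[-1].energy
    u_recomputed = configuration_energy(traj.final, params)
    assert u_sampled == pytest.approx(u_recomputed, abs=1e-6)


def test_tail_correction_off_lowers_density():
    """Dropping the attractive LJ tail must reduce the average density."""
    dens = {}
    for tail in (True, False):
        cfg = make_lattice_box(FixtureSpec(seed=3, n_waters=64))
        params = MCParams(n_steps=250_000, n_equilibration=150_000,
                          seed=11, tail_correction=tail)
        dens[tail] = run_npt(cfg, params).densities.mean()
    assert dens[False] < dens[True]


def test_detailed_balance_two_particle_histogram():
    """Two LJ-only waters at fixed volume: the sampled O-O separation
    histogram must match Boltzmann weights from direct quadrature."""
    cfg = make_lattice_box(FixtureSpec(seed=1, n_waters=2, box_edge=8.2,
                                       jitter=0.0))
    T = 160.0
    rc = 4.0
    params = MCParams(n_steps=1_500_000, n_equilibration=50_000,
                      temperature=T, coulomb_on=False, cutoff=rc,
                      tail_correction=False, volume_move_interval=0,
                      sample_stride=750_000, config_stride=150, seed=2)
    traj = run_npt(cfg, params)
    L = cfg.box_edge
    r_samples = []
    for c in traj.configurations:
        d = c.water_coords[0, 0] - c.water_coords[1, 0]
        d -= L * np.rint(d / L)
        r_samples.append(np.linalg.norm(d))
    r_samples = np.array(r_samples)

    spec = cfg.water
    sig, eps = spec.sigmas[0], spec.epsilons[0]
    beta = 1.0 / (KB_KJMOL * T)

    def u(r):
        sr6 = (sig / r) ** 6
        return np.where(r <= rc, 4 * eps * (sr6**2 - sr6), 0.0)

    edges = np.linspace(3.0, L / 2, 8)
    counts, _ = np.histogram(r_samples, bins=edges)
    probs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        rr = np.linspace(lo, hi, 200)
        probs.append(np.trapezoid(rr**2 * np.exp(-beta * u(rr)), rr))
    probs = np.array(probs) / sum(probs)
    inside = r_samples[(r_samples >= 3.0) & (r_samples <= L / 2)]
    observed = counts / counts.sum()
    # multinomial noise: compare at 5 sigma per bin
    sem = np.sqrt(probs * (1 - probs) / len(inside))
    assert np.all(np.abs(observed - probs) < 5 * sem + 0.02)


def test_autocorrelation_iid_noise():
    rng = np.random.default_rng(0)
    x = rng.normal(size=4000)
    stats = energy_autocorrelation(x)
    assert np.all(np.abs(stats["acf"][1:10]) < 2.0 / math.sqrt(len(x)) + 0.02)
    assert stats["interval"] <= 2


def test_autocorrelation_ar1_recovery():
    """AR(1), phi=0.9: recovered time ~ -1/ln(phi) within 20%."""
    phi = 0.9
    rng = np.random.default_rng(1)
    n = 200_000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.normal(size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    stats = energy_autocorrelation(x)
    tau_true = -1.0 / math.log(phi)
    assert stats["tau_exp"] == pytest.approx(tau_true, rel=0.2)
    # integrated time for AR(1) is (1+phi)/(1-phi) / 2 pairs with tau_int
    tau_int_true = 0.5 * (1 + phi) / (1 - phi)
    assert stats["tau_int"] == pytest.approx(tau_int_true, rel=0.25)


def test_thinning_by_interval_decorrelates():
    phi = 0.95
    rng = np.random.default_rng(2)
    n = 300_000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.normal(size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    stats = energy_autocorrelation(x)
    thin = x[:: stats["interval"]]
    lag1 = np.corrcoef(thin[:-1], thin[1:])[0, 1]
    assert abs(lag1) < 0.1


def test_constant_series_rejected():
    with pytest.raises(ValueError):
        energy_autocorrelation(np.ones(100))


def test_select_uncorrelated_counts_and_boundary(small_glycine_box):
    picks = select_uncorrelated(small_glycine_box, 5, interval=2)
    assert len(picks) == 5
    n_cfg = len(small_glycine_box.configurations)
    with pytest.raises(ValueError):
        select_uncorrelated(small_glycine_box, n_cfg + 1, interval=1)
    # stream of exactly n*interval - 1 cannot supply n picks
    with pytest.raises(ValueError):
        select_uncorrelated(small_glycine_box, (n_cfg + 2) // 2, interval=2)


def test_zero_temperature_rejected():
    with pytest.raises(ValueError):
        MCParams(temperature=0.0)
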