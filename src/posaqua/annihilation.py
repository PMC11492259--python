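"""Two-photon annihilation rates and positron-density diagnostics.

The spin-averaged annihilation rate at the Hartree-Fock level is
Gamma_HF = pi r0^2 c * sum_i S_i, with per-orbital density overlaps
S_i = int |psi_i|^2 |phi_p|^2 d^3r summed over both spins of each
closed-shell pair.  HF famously underestimates the short-range
electron-positron attraction, so orbital-energy-dependent enhancement
factors gamma_i (Green-Gribakin form) scale each orbital's contribution
in Gamma_ef.  Also here: radial probability densities of the positron
orbital, ESP-fitted (CHELPG-style) atomic charges, and cube-file export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import (ANGSTROM_PER_BOHR, ATOMIC_NUMBER, BOHR_PER_ANGSTROM,
                        VDW_RADII_A, annihilation_rate_constant_ns)
from .io import write_cube
from .qc import _md
from .qc.basis import CARTESIAN_COMPONENTS
from .qc.grids import angular_product_grid, becke_grid, eval_basis, eval_mos
from .qc.scf import TwoComponentSCFResult

__all__ = ["AnnihilationReport", "RPDResult", "density_overlaps", "gamma_hf",
           "enhancement_factors", "core_valence_split", "radial_probability",
           "esp_charges", "export_volumetric", "annihilation_report"]

log = logging.getLogger(__name__)

#: Green-Gribakin enhancement parameters (hartree-based), provisional
GG_A = 1.31
GG_B = 0.834
GG_C = 2.15

CORE_THRESHOLD_HA = -2.0


@dataclass
class AnnihilationReport:
    overlaps: np.ndarray            # per spatial orbital, single spin
    gamma_factors: np.ndarray       # per spatial orbital
    orbital_energies: np.ndarray
    gamma_hf: float                 # ns^-1
    gamma_ef: float                 # ns^-1
    gamma_hf_core: float
    gamma_ef_core: float
    spin_degeneracy: float
    grid_spec: dict = field(default_factory=dict)

    @property
    def core_fraction_hf(self) -> float:
        return self.gamma_hf_core / self.gamma_hf if self.gamma_hf else 0.0

    @property
    def core_fraction_ef(self) -> float:
        return self.gamma_ef_core / self.gamma_ef if self.gamma_ef else 0.0


@dataclass
class RPDResult:
    r: np.ndarray                   # Å
    density: np.ndarray             # Å^-1, integrates to 1
    r_max: float                    # Å
    rpd_max: float                  # Å^-1
    fwhm: float | None
    origin_atom: int


def density_overlaps(result: TwoComponentSCFResult,
                     n_radial: int = 60, n_theta: int = 17,
                     check_convergence: bool = True) -> np.ndarray:
    """Per-spatial-orbital overlaps S_i between occupied electron densities
    and the positron SOMO density, by Becke-partitioned quadrature.

    A second, denser grid is evaluated as a convergence check; a >1%
    drift raises (grid too coarse for this system).
    """
    s = _overlaps_on_grid(result, n_radial, n_theta)
    if check_convergence:
        s2 = _overlaps_on_grid(result, n_radial + 20, n_theta + 4)
        denom = max(s.sum(), 1e-300)
        drift = abs(s2.sum() - s.sum()) / denom
        if drift > 0.01:
            raise RuntimeError(
                f"quadrature not converged: total overlap drifts {drift:.1%} "
                "between grid levels; increase n_radial/n_theta")
        s = s2
    return s


def _overlaps_on_grid(result, n_radial, n_theta):
    sys_ = result.system
    if result.D_p is None:
        raise ValueError("result has no positron sector")
    # grid centers: atoms plus any positron-basis centers off the atoms
    centers = [tuple(x) for x in sys_.coords]
    elements = list(sys_.elements)
    for shell in sys_.positron_basis.shells:
        c = tuple(shell.center * ANGSTROM_PER_BOHR)
        if not any(np.allclose(c, x, atol=1e-6) for x in centers):
            centers.append(c)
            elements.append("H")        # generic soft radius
    pts, w = becke_grid(np.array(centers), elements, n_radial, n_theta)
    mo_e = eval_mos(sys_.electron_basis, result.e_mo_coeffs, pts,
                    indices=range(result.n_occ))
    phi_p = eval_mos(sys_.positron_basis, result.p_mo_coeffs, pts,
                     indices=[0])[:, 0]
    return np.einsum("g,gi,g->i", w, mo_e**2, phi_p**2)


def gamma_hf(overlaps, spin_degeneracy: float = 2.0) -> float:
    """Gamma_HF in ns^-1 from per-spatial-orbital overlaps (a.u.)."""
    return (annihilation_rate_constant_ns() * spin_degeneracy
            * float(np.sum(overlaps)))


def enhancement_factors(orbital_energies) -> np.ndarray:
    """Green-Gribakin enhancement gamma_i = 1 + sqrt(A/|eps|) + (B/|eps|)^C
    for bound orbitals (eps < 0)."""
    eps = np.asarray(orbital_energies, float)
    if np.any(eps >= 0):
        raise ValueError("enhancement factors need bound orbitals (eps < 0)")
    x = np.abs(eps)
    return 1.0 + np.sqrt(GG_A / x) + (GG_B / x) ** GG_C


def core_valence_split(overlaps, orbital_energies, gamma_factors=None,
                       threshold: float = CORE_THRESHOLD_HA,
                       spin_degeneracy: float = 2.0):
    """Split Gamma into core (eps < threshold) and valence parts.

    Returns dict with absolute rates (ns^-1) and core fractions for both
    the bare HF and enhanced rates."""
    eps = np.asarray(orbital_energies, float)
    s = np.asarray(overlaps, float)
    if gamma_factors is None:
        gamma_factors = enhancement_factors(eps)
    core = eps < threshold
    k = annihilation_rate_constant_ns() * spin_degeneracy
    out = {
        "gamma_hf_core": k * float(s[core].sum()),
        "gamma_hf_valence": k * float(s[~core].sum()),
        "gamma_ef_core": k * float((gamma_factors * s)[core].sum()),
        "gamma_ef_valence": k * float((gamma_factors * s)[~core].sum()),
        "n_core": int(core.sum()),
    }
    tot_hf = out["gamma_hf_core"] + out["gamma_hf_valence"]
    tot_ef = out["gamma_ef_core"] + out["gamma_ef_valence"]
    out["core_fraction_hf"] = out["gamma_hf_core"] / tot_hf if tot_hf else 0.0
    out["core_fraction_ef"] = out["gamma_ef_core"] / tot_ef if tot_ef else 0.0
    return out


def annihilation_report(result: TwoComponentSCFResult,
                        n_radial: int = 60, n_theta: int = 17,
                        core_threshold: float = CORE_THRESHOLD_HA,
                        check_convergence: bool = True) -> AnnihilationReport:
    """Full annihilation analysis of a converged positronic SCF result."""
    s = density_overlaps(result, n_radial, n_theta, check_convergence)
    eps = result.e_mo_energies[:result.n_occ]
    gam = enhancement_factors(eps)
    f = result.electron_occupancy
    split = core_valence_split(s, eps, gam, core_threshold, f)
    k = annihilation_rate_constant_ns() * f
    return AnnihilationReport(
        overlaps=s, gamma_factors=gam, orbital_energies=eps,
        gamma_hf=k * float(s.sum()),
        gamma_ef=k * float((gam * s).sum()),
        gamma_hf_core=split["gamma_hf_core"],
        gamma_ef_core=split["gamma_ef_core"],
        spin_degeneracy=f,
        grid_spec={"n_radial": n_radial, "n_theta": n_theta})


def radial_probability(result: TwoComponentSCFResult, origin_atom: int,
                       r_max_angstrom: float = 20.0, n_r: int = 400,
                       n_theta: int = 24) -> RPDResult:
    """Radial probability density of the positron orbital about an atom.

    RPD(r) = r^2 * int |phi_p(r, Omega)|^2 dOmega, reported on an Å grid
    (Å^-1 units, integrates to ~1 up to truncation).
    """
    sys_ = result.system
    if result.D_p is None:
        raise ValueError("result has no positron sector")
    if not (0 <= origin_atom < sys_.n_atoms):
        raise ValueError(f"origin atom {origin_atom} not in system")
    origin = sys_.coords_bohr()[origin_atom]
    dirs, wts = angular_product_grid(n_theta)
    r_bohr = np.linspace(1e-4, r_max_angstrom * BOHR_PER_ANGSTROM, n_r)
    dens_bohr = np.empty(n_r)
    # evaluate shell-by-shell to bound memory
    block = 64
    for i0 in range(0, n_r, block):
        rr = r_bohr[i0:i0 + block]
        pts = (origin[None, None, :]
               + rr[:, None, None] * dirs[None, :, :]).reshape(-1, 3)
        phi = eval_mos(sys_.positron_basis, result.p_mo_coeffs, pts,
                       indices=[0])[:, 0].reshape(len(rr), -1)
        dens_bohr[i0:i0 + len(rr)] = rr**2 * (phi**2 @ wts)
    r_a = r_bohr * ANGSTROM_PER_BOHR
    dens_a = dens_bohr * BOHR_PER_ANGSTROM
    ipk = int(np.argmax(dens_a))
    fwhm = _fwhm(r_a, dens_a, ipk)
    return RPDResult(r=r_a, density=dens_a, r_max=float(r_a[ipk]),
                     rpd_max=float(dens_a[ipk]), fwhm=fwhm,
                     origin_atom=origin_atom)


def _fwhm(x, y, ipk):
    half = y[ipk] / 2.0
    left = right = None
    for i in range(ipk, 0, -1):
        if y[i - 1] <= half:
            left = np.interp(half, [y[i - 1], y[i]], [x[i - 1], x[i]])
            break
    for i in range(ipk, len(y) - 1):
        if y[i + 1] <= half:
            right = np.interp(half, [y[i + 1], y[i]], [x[i + 1], x[i]])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def esp_charges(result: TwoComponentSCFResult, spacing: float = 0.3,
                shell_width: float = 2.8, include_positron: bool = False):
    """CHELPG-style atomic charges: least-squares fit of point charges to
    the quantum electrostatic potential on a cubic grid between the vdW
    surface and an outer envelope, constrained to the total charge.

    By default the ESP is that of nuclei + electrons only (the positron
    is excluded, matching the convention of charging analyses of the
    parent electronic density).
    """
    sys_ = result.system
    coords = sys_.coords
    vdw = np.array([VDW_RADII_A.get(e, 1.5) for e in sys_.elements])
    lo = coords.min(axis=0) - shell_width
    hi = coords.max(axis=0) + shell_width
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(G[:, None, :] - coords[None, :, :], axis=-1)
    keep = (d >= vdw[None, :]).all(axis=1) & (d <= shell_width).any(axis=1)
    pts = G[keep]
    dk = d[keep]
    if len(pts) < sys_.n_atoms + 1:
        raise ValueError("too few ESP grid points; decrease spacing")

    v = _esp_values(result, pts, include_positron)
    # fit: minimize |A q - v|^2 with sum(q) = q_total
    A = 1.0 / (dk * BOHR_PER_ANGSTROM)
    q_total = float(sys_.nuclear_charges.sum() - sys_.n_electrons
                    + (sys_.n_positrons if include_positron else 0))
    n = sys_.n_atoms
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A.T @ A
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    rhs = np.zeros(n + 1)
    rhs[:n] = A.T @ v
    rhs[n] = q_total
    sol = np.linalg.solve(M, rhs)
    charges = sol[:n]
    rms = float(np.sqrt(np.mean((A @ charges - v) ** 2)))
    return charges, {"rms": rms, "n_points": len(pts),
                     "total_charge": q_total}


def _esp_values(result: TwoComponentSCFResult, points_angstrom,
                include_positron: bool) -> np.ndarray:
    """Quantum ESP (hartree/e) at the points: nuclei + electron density
    (+ optionally the positron density)."""
    sys_ = result.system
    pts = np.asarray(points_angstrom, float) * BOHR_PER_ANGSTROM
    centers = sys_.coords_bohr()
    v = np.zeros(len(pts))
    for z, c in zip(sys_.nuclear_charges, centers):
        v += z / np.linalg.norm(pts - c[None, :], axis=1)
    if result.D_e is not None:
        v -= result.electron_occupancy * _density_potential(
            sys_.electron_basis, result.D_e, pts)
    if include_positron and result.D_p is not None:
        v += _density_potential(sys_.positron_basis, result.D_p, pts)
    return v


def _density_potential(basis, D, pts_bohr) -> np.ndarray:
    """sum_munu D_munu (mu|1/|r-g||nu) at grid points (hartree/e)."""
    comp = {l: np.array(CARTESIAN_COMPONENTS[l], dtype=np.int64)
            for l in (0, 1, 2)}
    out = np.zeros(len(pts_bohr))
    off = basis.offsets()
    shells = basis.shells
    for i in range(len(shells)):
        si = shells[i]
        for j in range(i, len(shells)):
            sj = shells[j]
            Dblk = D[off[i]:off[i] + si.n_components,
                     off[j]:off[j] + sj.n_components].copy()
            if j != i:
                Dblk = 2.0 * Dblk        # symmetric off-diagonal pair
            _md.esp_pair_block(si.l, sj.l, si.center, sj.center,
                               si.exps, si.coefs, sj.exps, sj.coefs,
                               comp[si.l], comp[sj.l], pts_bohr, Dblk, out)
    return out


def export_volumetric(result: TwoComponentSCFResult, field_name: str,
                      path, spacing: float = 0.4, margin: float = 6.0):
    """Write a cube file of ``field_name`` in
    {"positron_orbital", "positron_density", "contact_density", "esp"}.

    contact density = rho_e(r) * |phi_p(r)|^2.
    """
    sys_ = result.system
    lo = (sys_.coords.min(axis=0) - margin) * BOHR_PER_ANGSTROM
    hi = (sys_.coords.max(axis=0) + margin) * BOHR_PER_ANGSTROM
    ns = np.maximum(((hi - lo) / (spacing * BOHR_PER_ANGSTROM)).astype(int)
                    + 1, 2)
    axes_pts = [np.linspace(lo[k], hi[k], ns[k]) for k in range(3)]
    P = np.stack(np.meshgrid(*axes_pts, indexing="ij"), axis=-1).reshape(-1, 3)

    if field_name in ("positron_orbital", "positron_density",
                      "contact_density"):
        if result.D_p is None:
            raise ValueError("no positron sector")
        phi = eval_mos(sys_.positron_basis, result.p_mo_coeffs, P,
                       indices=[0])[:, 0]
    if field_name == "positron_orbital":
        data = phi
    elif field_name == "positron_density":
        data = phi**2
    elif field_name == "contact_density":
        ao = eval_basis(sys_.electron_basis, P)
        rho_e = result.electron_occupancy * np.einsum(
            "gm,mn,gn->g", ao, result.D_e, ao, optimize=True)
        data = rho_e * phi**2
    elif field_name == "esp":
        data = _esp_values(result, P * ANGSTROM_PER_BOHR, False)
    else:
        raise ValueError(f"unknown field {field_name!r}")

    steps = np.diag([(hi[k] - lo[k]) / (ns[k] - 1) for k in range(3)])
    atoms = [(ATOMIC_NUMBER.get(e, 1), *xyz)
             for e, xyz in zip(sys_.elements, sys_.coords_bohr())]
    with open(path, "w") as fh:
        write_cube(fh, atoms, lo, steps, data.reshape(ns),
                   comment=f"posaqua {field_name}")
    return {"shape": tuple(int(x) for x in ns),
            "voxel_volume_bohr3": float(np.prod(np.diag(steps)))}
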