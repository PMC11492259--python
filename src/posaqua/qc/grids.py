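"""Multicenter numerical integration grids and basis-function evaluation.

Atom-centered grids use Gauss-Chebyshev (second kind) radial points with
the standard rational mapping, a Gauss-Legendre x uniform-phi angular
product grid, and Becke's fuzzy-cell partition (three smoothing passes,
Bragg-radius size adjustment).  The product angular grid integrates
spherical harmonics exactly up to degree 2*n_theta - 1, comparable to the
customary Lebedev grids at the sizes used here.
"""

from __future__ import annotations

import numpy as np

from ..constants import BRAGG_RADII_A, BOHR_PER_ANGSTROM
from .basis import CARTESIAN_COMPONENTS, BasisSet

__all__ = ["becke_grid", "atom_grid", "eval_basis", "eval_mos",
           "angular_product_grid"]


def _radial_grid(n_radial: int, r_m: float):
    """Gauss-Chebyshev-2 radial grid mapped to (0, inf); weights include
    the r^2 volume element and the mapping Jacobian."""
    i = np.arange(1, n_radial + 1)
    theta = i * np.pi / (n_radial + 1)
    x = np.cos(theta)
    w_gc = np.pi / (n_radial + 1) * np.sin(theta) ** 2
    r = r_m * (1.0 + x) / (1.0 - x)
    jac = 2.0 * r_m / (1.0 - x) ** 2
    w = w_gc / np.sqrt(1.0 - x * x) * r * r * jac
    return r, w


def angular_product_grid(n_theta: int):
    """Unit-sphere quadrature: Gauss-Legendre in cos(theta) x uniform phi.

    Returns (directions (M,3), weights summing to 4*pi)."""
    mu, w_mu = np.polynomial.legendre.leggauss(n_theta)
    n_phi = 2 * n_theta
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - mu**2)
    dirs = np.empty((n_theta * n_phi, 3))
    wts = np.empty(n_theta * n_phi)
    k = 0
    for it in range(n_theta):
        for ip in range(n_phi):
            dirs[k] = (st[it] * np.cos(phi[ip]), st[it] * np.sin(phi[ip]),
                       mu[it])
            wts[k] = w_mu[it] * (2.0 * np.pi / n_phi)
            k += 1
    return dirs, wts


def atom_grid(center_bohr, r_m: float, n_radial: int, n_theta: int):
    """Single-center grid: points (N,3) and weights (volume measure)."""
    r, wr = _radial_grid(n_radial, r_m)
    dirs, wa = angular_product_grid(n_theta)
    pts = (center_bohr[None, None, :]
           + r[:, None, None] * dirs[None, :, :]).reshape(-1, 3)
    w = (wr[:, None] * wa[None, :]).reshape(-1)
    return pts, w


def _becke_step(mu):
    p = mu
    for _ in range(3):
        p = 1.5 * p - 0.5 * p**3
    return 0.5 * (1.0 - p)


def becke_grid(centers_angstrom, elements, n_radial: int = 60,
               n_theta: int = 17):
    """Becke-partitioned multicenter grid over the given atoms.

    Returns (points_bohr (N,3), weights (N)); integrating a density on it
    approximates the full-space integral.
    """
    centers = np.asarray(centers_angstrom, float).reshape(-1, 3) \
        * BOHR_PER_ANGSTROM
    n_at = len(centers)
    radii = np.array([BRAGG_RADII_A.get(e, 0.8) * BOHR_PER_ANGSTROM
                      for e in elements])
    all_pts, all_w = [], []
    # pairwise size-adjustment offsets
    a_ij = np.zeros((n_at, n_at))
    for i in range(n_at):
        for j in range(n_at):
            if i == j:
                continue
            chi = radii[i] / radii[j]
            u = (chi - 1.0) / (chi + 1.0)
            a = u / (u * u - 1.0)
            a_ij[i, j] = np.clip(a, -0.5, 0.5)

    dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    for i in range(n_at):
        pts, w = atom_grid(centers[i], radii[i], n_radial, n_theta)
        if n_at == 1:
            all_pts.append(pts)
            all_w.append(w)
            continue
        d_atom = np.linalg.norm(pts[:, None, :] - centers[None, :, :],
                                axis=-1)                       # (N, n_at)
        P = np.ones((len(pts), n_at))
        for ia in range(n_at):
            for ja in range(n_at):
                if ia == ja:
                    continue
                mu = (d_atom[:, ia] - d_atom[:, ja]) / dist[ia, ja]
                mu = mu + a_ij[ia, ja] * (1.0 - mu**2)
                P[:, ia] *= _becke_step(mu)
        cell = P[:, i] / P.sum(axis=1)
        all_pts.append(pts)
        all_w.append(w * cell)
    return np.concatenate(all_pts), np.concatenate(all_w)


def eval_basis(basis: BasisSet, points_bohr: np.ndarray) -> np.ndarray:
    """Values of every (normalized) Cartesian AO at the points: (N, nbf)."""
    from ._md import comp_norm
    pts = np.asarray(points_bohr, float).reshape(-1, 3)
    out = np.empty((len(pts), basis.n_functions))
    col = 0
    for shell in basis.shells:
        d = pts - shell.center[None, :]
        r2 = np.einsum("ni,ni->n", d, d)
        for comp in CARTESIAN_COMPONENTS[shell.l]:
            coef = sum(c * comp_norm(a, *comp) * np.exp(-a * r2)
                       for a, c in zip(shell.exps, shell.coefs))
            poly = (d[:, 0] ** comp[0] * d[:, 1] ** comp[1]
                    * d[:, 2] ** comp[2])
            out[:, col] = poly * coef
            col += 1
    return out


def eval_mos(basis: BasisSet, C: np.ndarray, points_bohr: np.ndarray,
             indices=None) -> np.ndarray:
    """Molecular-orbital values at points: (N, n_selected)."""
    ao = eval_basis(basis, points_bohr)
    if indices is not None:
        C = C[:, indices]
    return ao @ C
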