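"""Numba kernels for the rigid-body NpT Monte Carlo engine.

State layout: molecules are contiguous site ranges in flat arrays.  The
cutoff and the minimum-image convention act on the distance between the
*reference sites* (first heavy atom) of a molecule pair; the same image
shift is applied to every site pair so molecules interact as wholes and
remain charge-neutral groups under truncation.
"""

import math

import numpy as np
from numba import njit

from .constants import COULOMB_KJ_A


@njit(cache=True)
def pair_energy_kernel(coords, q, sig, ehalf, a0, a1, b0, b1,
                       ref_a, ref_b, box_edge, rc2, krf):
    """LJ + Coulomb energy between molecules [a0:a1) and [b0:b1).

    ``krf`` > 0 switches on the conducting-boundary reaction-field
    correction q_i q_j (krf r^2 - 1/rc - krf rc^2) inside the cutoff
    (the constant shift cancels exactly for neutral molecule pairs).
    """
    dxr = coords[ref_a, 0] - coords[ref_b, 0]
    dyr = coords[ref_a, 1] - coords[ref_b, 1]
    dzr = coords[ref_a, 2] - coords[ref_b, 2]
    sx = sy = sz = 0.0
    if box_edge > 0.0:
        sx = box_edge * round(dxr / box_edge)
        sy = box_edge * round(dyr / box_edge)
        sz = box_edge * round(dzr / box_edge)
    d2 = (dxr - sx)**2 + (dyr - sy)**2 + (dzr - sz)**2
    if rc2 > 0.0 and d2 > rc2:
        return 0.0
    e = 0.0
    shift_c = 0.0
    if krf > 0.0 and rc2 > 0.0:
        shift_c = 1.0 / math.sqrt(rc2) + krf * rc2
    for i in range(a0, a1):
        for j in range(b0, b1):
            rx = coords[i, 0] - coords[j, 0] - sx
            ry = coords[i, 1] - coords[j, 1] - sy
            rz = coords[i, 2] - coords[j, 2] - sz
            r2 = rx * rx + ry * ry + rz * rz
            r = math.sqrt(r2)
            e += COULOMB_KJ_A * q[i] * q[j] * (1.0 / r + krf * r2 - shift_c)
            eij = ehalf[i] * ehalf[j]
            if eij > 0.0:
                sij = 0.5 * (sig[i] + sig[j])
                sr2 = sij * sij / r2
                sr6 = sr2 * sr2 * sr2
                e += 4.0 * eij * (sr6 * sr6 - sr6)
    return e


@njit(cache=True)
def mol_energy(im, coords, q, sig, ehalf, mstart, mend, ref, box_edge, rc2, krf):
    """Interaction energy of molecule ``im`` with all other molecules."""
    e = 0.0
    nmol = mstart.shape[0]
    for jm in range(nmol):
        if jm == im:
            continue
        e += pair_energy_kernel(coords, q, sig, ehalf,
                                mstart[im], mend[im], mstart[jm], mend[jm],
                                ref[im], ref[jm], box_edge, rc2, krf)
    return e


@njit(cache=True)
def total_energy(coords, q, sig, ehalf, mstart, mend, ref, box_edge, rc2, krf):
    e = 0.0
    nmol = mstart.shape[0]
    for im in range(nmol):
        for jm in range(im + 1, nmol):
            e += pair_energy_kernel(coords, q, sig, ehalf,
                                    mstart[im], mend[im], mstart[jm], mend[jm],
                                    ref[im], ref[jm], box_edge, rc2, krf)
    return e


@njit(cache=True)
def _rotate_molecule(coords, m0, m1, ref, ux, uy, uz, ang):
    """Rotate sites of a molecule about an axis through its reference site."""
    c = math.cos(ang)
    s = math.sin(ang)
    t = 1.0 - c
    r00 = c + ux * ux * t
    r01 = ux * uy * t - uz * s
    r02 = ux * uz * t + uy * s
    r10 = uy * ux * t + uz * s
    r11 = c + uy * uy * t
    r12 = uy * uz * t - ux * s
    r20 = uz * ux * t - uy * s
    r21 = uz * uy * t + ux * s
    r22 = c + uz * uz * t
    ox = coords[ref, 0]
    oy = coords[ref, 1]
    oz = coords[ref, 2]
    for i in range(m0, m1):
        x = coords[i, 0] - ox
        y = coords[i, 1] - oy
        z = coords[i, 2] - oz
        coords[i, 0] = ox + r00 * x + r01 * y + r02 * z
        coords[i, 1] = oy + r10 * x + r11 * y + r12 * z
        coords[i, 2] = oz + r20 * x + r21 * y + r22 * z


@njit(cache=True)
def _random_unit_vector():
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        z = 2.0 * np.random.random() - 1.0
        n2 = x * x + y * y + z * z
        if 1e-12 < n2 <= 1.0:
            n = math.sqrt(n2)
            return x / n, y / n, z / n


@njit(cache=True)
def tail_energy(volume, c9, c3, rc):
    """Standard LJ long-range correction beyond the spherical cutoff."""
    if volume <= 0.0:
        return 0.0
    return (2.0 * math.pi / volume) * (c9 / (9.0 * rc**9) - c3 / (3.0 * rc**3))


@njit(cache=True)
def run_mc_chunk(coords, q, sig, ehalf, mstart, mend, ref,
                 movable, box_edge, rc, beta, pressure,
                 n_steps, dt, dang, dvol, vol_interval,
                 sample_stride, config_stride, c9, c3,
                 tune, seed, use_tail, krf):
    """Run ``n_steps`` Metropolis NpT steps in place.

    Returns (energies, volumes, sample_steps, saved_coords, saved_edges,
             acc_counts, att_counts, dt, dang, dvol, box_edge, u_current).
    acc/att counts: [translation+rotation, volume].
    """
    np.random.seed(seed)
    nmol = mstart.shape[0]
    nmov = movable.shape[0]
    rc2 = rc * rc

    u = total_energy(coords, q, sig, ehalf, mstart, mend, ref, box_edge, rc2,
                     krf)
    if use_tail:
        u += tail_energy(box_edge**3, c9, c3, rc)

    n_samples = n_steps // sample_stride
    energies = np.empty(n_samples)
    volumes = np.empty(n_samples)
    sample_steps = np.empty(n_samples, dtype=np.int64)
    n_cfg = n_steps // config_stride if config_stride > 0 else 0
    saved_coords = np.empty((n_cfg, coords.shape[0], 3))
    saved_edges = np.empty(n_cfg)

    acc = np.zeros(2, dtype=np.int64)
    att = np.zeros(2, dtype=np.int64)
    acc_win = np.zeros(2, dtype=np.int64)
    att_win = np.zeros(2, dtype=np.int64)

    isample = 0
    icfg = 0
    for step in range(n_steps):
        do_volume = vol_interval > 0 and (step + 1) % vol_interval == 0
        if do_volume:
            att[1] += 1
            att_win[1] += 1
            v_old = box_edge**3
            v_new = v_old + (2.0 * np.random.random() - 1.0) * dvol
            if v_new > 8.0 * rc**3:      # keep rc <= L/2
                edge_new = v_new ** (1.0 / 3.0)
                s = edge_new / box_edge
                old = coords.copy()
                for im in range(nmol):
                    r0 = ref[im]
                    dxs = (s - 1.0) * coords[r0, 0]
                    dys = (s - 1.0) * coords[r0, 1]
                    dzs = (s - 1.0) * coords[r0, 2]
                    for i in range(mstart[im], mend[im]):
                        coords[i, 0] += dxs
                        coords[i, 1] += dys
                        coords[i, 2] += dzs
                u_new = total_energy(coords, q, sig, ehalf, mstart, mend,
                                     ref, edge_new, rc2, krf)
                if use_tail:
                    u_new += tail_energy(v_new, c9, c3, rc)
                arg = (-beta * (u_new - u + pressure * (v_new - v_old))
                       + nmol * math.log(v_new / v_old))
                if arg > 0.0 or np.random.random() < math.exp(arg):
                    u = u_new
                    box_edge = edge_new
                    acc[1] += 1
                    acc_win[1] += 1
                else:
                    coords[:, :] = old
        else:
            att[0] += 1
            att_win[0] += 1
            im = movable[np.random.randint(nmov)]
            m0 = mstart[im]
            m1 = mend[im]
            u_old_m = mol_energy(im, coords, q, sig, ehalf, mstart, mend,
                                 ref, box_edge, rc2, krf)
            old = coords[m0:m1].copy()
            # translation
            coords[m0:m1, 0] += (2.0 * np.random.random() - 1.0) * dt
            coords[m0:m1, 1] += (2.0 * np.random.random() - 1.0) * dt
            coords[m0:m1, 2] += (2.0 * np.random.random() - 1.0) * dt
            # rotation (skip single-site molecules)
            if m1 - m0 > 1:
                ux, uy, uz = _random_unit_vector()
                ang = (2.0 * np.random.random() - 1.0) * dang
                _rotate_molecule(coords, m0, m1, ref[im], ux, uy, uz, ang)
            u_new_m = mol_energy(im, coords, q, sig, ehalf, mstart, mend,
                                 ref, box_edge, rc2, krf)
            du = u_new_m - u_old_m
            if du <= 0.0 or np.random.random() < math.exp(-beta * du):
                u += du
                acc[0] += 1
                acc_win[0] += 1
                # wrap molecule back into the box by its reference site
                for k in range(3):
                    sft = box_edge * math.floor(coords[ref[im], k] / box_edge)
                    if sft != 0.0:
                        for i in range(m0, m1):
                            coords[i, k] -= sft
            else:
                coords[m0:m1] = old

        if tune and (step + 1) % 2000 == 0:
            if att_win[0] > 0:
                frac = acc_win[0] / att_win[0]
                if frac > 0.45:
                    dt = min(dt * 1.08, 3.0)
                    dang = min(dang * 1.08, math.pi)
                elif frac < 0.35:
                    dt = max(dt * 0.92, 0.01)
                    dang = max(dang * 0.92, 0.01)
            if att_win[1] > 4:
                fracv = acc_win[1] / att_win[1]
                if fracv > 0.45:
                    dvol = dvol * 1.1
                elif fracv < 0.35:
                    dvol = max(dvol * 0.9, 1.0)
            acc_win[:] = 0
            att_win[:] = 0

        if (step + 1) % sample_stride == 0 and isample < n_samples:
            energies[isample] = u
            volumes[isample] = box_edge**3
            sample_steps[isample] = step + 1
            isample += 1
        if config_stride > 0 and (step + 1) % config_stride == 0 \
                and icfg < n_cfg:
            saved_coords[icfg] = coords
            saved_edges[icfg] = box_edge
            icfg += 1

    return (energies, volumes, sample_steps, saved_coords, saved_edges,
            acc, att, dt, dang, dvol, box_edge, u)
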