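"""McMurchie–Davidson evaluation of Gaussian integrals (numba kernels).

Hermite expansion coefficients E_t^{ij} and the Hermite Coulomb tensor
R_{tuv} give overlap, kinetic, multipole, point-charge attraction and
(four-index) Coulomb repulsion integrals for Cartesian shells up to d.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _df(n):
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


@njit(cache=True)
def comp_norm(a, lx, ly, lz):
    """Normalization of a primitive Cartesian Gaussian component."""
    l = lx + ly + lz
    return ((2.0 * a / math.pi) ** 0.75 * (4.0 * a) ** (l / 2.0)
            / math.sqrt(_df(2 * lx - 1) * _df(2 * ly - 1) * _df(2 * lz - 1)))


@njit(cache=True)
def boys(mmax, T, out):
    """Boys functions F_0..F_mmax by series + downward recursion."""
    if T < 35.0:
        # series for F_mmax, then downward
        m = mmax
        s = 1.0 / (m + 0.5)
        term = s
        k = 1
        while True:
            term *= T / (m + k + 0.5)
            s += term
            if term < 1e-17 * s or k > 300:
                break
            k += 1
        emt = math.exp(-T)
        out[mmax] = 0.5 * s * emt
        for n in range(mmax - 1, -1, -1):
            out[n] = (2.0 * T * out[n + 1] + emt) / (2 * n + 1)
    else:
        out[0] = 0.5 * math.sqrt(math.pi / T)
        for n in range(1, mmax + 1):
            out[n] = out[n - 1] * (2 * n - 1) / (2.0 * T)


@njit(cache=True)
def e_table(la, lb, a, b, AB):
    """Hermite expansion coefficients E[i,j,t] for one axis."""
    p = a + b
    mu = a * b / p
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = math.exp(-mu * AB * AB)
    XPA = -b * AB / p      # P - A with A-B = AB ... sign: P = (aA+bB)/p
    XPB = a * AB / p       # P - B
    # note: AB here is A - B, so P - A = -(b/p)(A-B), P - B = (a/p)(A-B)
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + j + 1):
                    v = XPA * E[i - 1, 0, t]
                    if t > 0:
                        v += E[i - 1, 0, t - 1] / (2.0 * p)
                    v += (t + 1) * E[i - 1, 0, t + 1]
                    E[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = XPB * E[i, j - 1, t]
                    if t > 0:
                        v += E[i, j - 1, t - 1] / (2.0 * p)
                    v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v
    return E


@njit(cache=True)
def r_tensor(L, p, X, Y, Z):
    """Hermite Coulomb tensor R^0_{tuv} up to t+u+v = L."""
    T = p * (X * X + Y * Y + Z * Z)
    F = np.zeros(L + 1)
    boys(L, T, F)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))     # [n, t, u, v]
    fac = 1.0
    for n in range(L + 1):
        R[n, 0, 0, 0] = fac * F[n]
        fac *= -2.0 * p
    for total in range(1, L + 1):
        for t in range(total + 1):
            for u in range(total - t + 1):
                v = total - t - u
                for n in range(L - total, -1, -1):
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


@njit(cache=True)
def overlap_block(la, lb, A, B, aexp, acoef, bexp, bcoef, ca, cb):
    na, nb = ca.shape[0], cb.shape[0]
    out = np.zeros((na, nb))
    for ip in range(aexp.shape[0]):
        a = aexp[ip]
        for jp in range(bexp.shape[0]):
            b = bexp[jp]
            p = a + b
            Ex = e_table(la, lb, a, b, A[0] - B[0])
            Ey = e_table(la, lb, a, b, A[1] - B[1])
            Ez = e_table(la, lb, a, b, A[2] - B[2])
            pref = acoef[ip] * bcoef[jp] * (math.pi / p) ** 1.5
            for ia in range(na):
                nai = comp_norm(a, ca[ia, 0], ca[ia, 1], ca[ia, 2])
                for ib in range(nb):
                    nbj = comp_norm(b, cb[ib, 0], cb[ib, 1], cb[ib, 2])
                    out[ia, ib] += (pref * nai * nbj
                                    * Ex[ca[ia, 0], cb[ib, 0], 0]
                                    * Ey[ca[ia, 1], cb[ib, 1], 0]
                                    * Ez[ca[ia, 2], cb[ib, 2], 0])
    return out


@njit(cache=True)
def _kin1d(i, j, a, b, E):
    """1D kinetic matrix element over Hermite overlaps (no (pi/p)^1/2)."""
    # T_ij = -2 b^2 S_{i,j+2} + b(2j+1) S_{i,j} - j(j-1)/2 S_{i,j-2}
    t = -2.0 * b * b * E[i, j + 2, 0] + b * (2 * j + 1) * E[i, j, 0]
    if j >= 2:
        t -= 0.5 * j * (j - 1) * E[i, j - 2, 0]
    return t


@njit(cache=True)
def kinetic_block(la, lb, A, B, aexp, acoef, bexp, bcoef, ca, cb):
    na, nb = ca.shape[0], cb.shape[0]
    out = np.zeros((na, nb))
    for ip in range(aexp.shape[0]):
        a = aexp[ip]
        for jp in range(bexp.shape[0]):
            b = bexp[jp]
            p = a + b
            # E tables with j up to lb+2
            Ex = e_table(la, lb + 2, a, b, A[0] - B[0])
            Ey = e_table(la, lb + 2, a, b, A[1] - B[1])
            Ez = e_table(la, lb + 2, a, b, A[2] - B[2])
            pref = acoef[ip] * bcoef[jp] * (math.pi / p) ** 1.5
            for ia in range(na):
                nai = comp_norm(a, ca[ia, 0], ca[ia, 1], ca[ia, 2])
                for ib in range(nb):
                    nbj = comp_norm(b, cb[ib, 0], cb[ib, 1], cb[ib, 2])
                    tx = _kin1d(ca[ia, 0], cb[ib, 0], a, b, Ex)
                    ty = _kin1d(ca[ia, 1], cb[ib, 1], a, b, Ey)
                    tz = _kin1d(ca[ia, 2], cb[ib, 2], a, b, Ez)
                    sx = Ex[ca[ia, 0], cb[ib, 0], 0]
                    sy = Ey[ca[ia, 1], cb[ib, 1], 0]
                    sz = Ez[ca[ia, 2], cb[ib, 2], 0]
                    out[ia, ib] += pref * nai * nbj * (
                        tx * sy * sz + sx * ty * sz + sx * sy * tz)
    return out


@njit(cache=True)
def moment_block(la, lb, A, B, aexp, acoef, bexp, bcoef, ca, cb):
    """First-moment (x, y, z) integrals about the origin: (3, na, nb)."""
    na, nb = ca.shape[0], cb.shape[0]
    out = np.zeros((3, na, nb))
    for ip in range(aexp.shape[0]):
        a = aexp[ip]
        for jp in range(bexp.shape[0]):
            b = bexp[jp]
            p = a + b
            P = (a * A + b * B) / p
            Ex = e_table(la, lb, a, b, A[0] - B[0])
            Ey = e_table(la, lb, a, b, A[1] - B[1])
            Ez = e_table(la, lb, a, b, A[2] - B[2])
            pref = acoef[ip] * bcoef[jp] * (math.pi / p) ** 1.5
            for ia in range(na):
                nai = comp_norm(a, ca[ia, 0], ca[ia, 1], ca[ia, 2])
                for ib in range(nb):
                    nbj = comp_norm(b, cb[ib, 0], cb[ib, 1], cb[ib, 2])
                    sx = Ex[ca[ia, 0], cb[ib, 0], 0]
                    sy = Ey[ca[ia, 1], cb[ib, 1], 0]
                    sz = Ez[ca[ia, 2], cb[ib, 2], 0]
                    mx = Ex[ca[ia, 0], cb[ib, 0], 1] + P[0] * sx
                    my = Ey[ca[ia, 1], cb[ib, 1], 1] + P[1] * sy
                    mz = Ez[ca[ia, 2], cb[ib, 2], 1] + P[2] * sz
                    c = pref * nai * nbj
                    out[0, ia, ib] += c * mx * sy * sz
                    out[1, ia, ib] += c * sx * my * sz
                    out[2, ia, ib] += c * sx * sy * mz
    return out


@njit(cache=True)
def attraction_block(la, lb, A, B, aexp, acoef, bexp, bcoef, ca, cb,
                     centers, charges):
    """Sum_k q_k * (a| 1/|r-C_k| |b): positive-charge attraction integrals
    (returned with the convention that the matrix itself is positive for
    positive q; callers apply particle-sign factors)."""
    na, nb = ca.shape[0], cb.shape[0]
    L = la + lb
    out = np.zeros((na, nb))
    for ip in range(aexp.shape[0]):
        a = aexp[ip]
        for jp in range(bexp.shape[0]):
            b = bexp[jp]
            p = a + b
            P = (a * A + b * B) / p
            Ex = e_table(la, lb, a, b, A[0] - B[0])
            Ey = e_table(la, lb, a, b, A[1] - B[1])
            Ez = e_table(la, lb, a, b, A[2] - B[2])
            pref = acoef[ip] * bcoef[jp] * 2.0 * math.pi / p
            for k in range(centers.shape[0]):
                R = r_tensor(L, p, P[0] - centers[k, 0],
                             P[1] - centers[k, 1], P[2] - centers[k, 2])
                for ia in range(na):
                    nai = comp_norm(a, ca[ia, 0], ca[ia, 1], ca[ia, 2])
                    for ib in range(nb):
                        nbj = comp_norm(b, cb[ib, 0], cb[ib, 1], cb[ib, 2])
                        acc = 0.0
                        for t in range(ca[ia, 0] + cb[ib, 0] + 1):
                            et = Ex[ca[ia, 0], cb[ib, 0], t]
                            for u in range(ca[ia, 1] + cb[ib, 1] + 1):
                                eu = Ey[ca[ia, 1], cb[ib, 1], u]
                                for v in range(ca[ia, 2] + cb[ib, 2] + 1):
                                    acc += (et * eu
                                            * Ez[ca[ia, 2], cb[ib, 2], v]
                                            * R[t, u, v])
                        out[ia, ib] += charges[k] * pref * nai * nbj * acc
    return out


@njit(cache=True)
def esp_pair_block(la, lb, A, B, aexp, acoef, bexp, bcoef, ca, cb,
                   points, Dblock, out):
    """Accumulate sum_{mu nu in block} D_munu (mu|1/|r-g||nu) into out[g]."""
    na, nb = ca.shape[0], cb.shape[0]
    L = la + lb
    for ip in range(aexp.shape[0]):
        a = aexp[ip]
        for jp in range(bexp.shape[0]):
            b = bexp[jp]
            p = a + b
            P = (a * A + b * B) / p
            Ex = e_table(la, lb, a, b, A[0] - B[0])
            Ey = e_table(la, lb, a, b, A[1] - B[1])
            Ez = e_table(la, lb, a, b, A[2] - B[2])
            pref = acoef[ip] * bcoef[jp] * 2.0 * math.pi / p
            for g in range(points.shape[0]):
                R = r_tensor(L, p, P[0] - points[g, 0], P[1] - points[g, 1],
                             P[2] - points[g, 2])
                acc_g = 0.0
                for ia in range(na):
                    nai = comp_norm(a, ca[ia, 0], ca[ia, 1], ca[ia, 2])
                    for ib in range(nb):
                        nbj = comp_norm(b, cb[ib, 0], cb[ib, 1], cb[ib, 2])
                        acc = 0.0
                        for t in range(ca[ia, 0] + cb[ib, 0] + 1):
                            et = Ex[ca[ia, 0], cb[ib, 0], t]
                            for u in range(ca[ia, 1] + cb[ib, 1] + 1):
                                eu = Ey[ca[ia, 1], cb[ib, 1], u]
                                for v in range(ca[ia, 2] + cb[ib, 2] + 1):
                                    acc += (et * eu
                                            * Ez[ca[ia, 2], cb[ib, 2], v]
                                            * R[t, u, v])
                        acc_g += nai * nbj * acc * Dblock[ia, ib]
                out[g] += pref * acc_g


@njit(cache=True)
def eri_block(la, lb, lc, ld, A, B, C, D,
              aexp, acoef, bexp, bcoef, cexp, ccoef, dexp, dcoef,
              ca, cb, cc, cd):
    """Contracted two-body Coulomb repulsion block (ab|cd)."""
    na, nb, nc, nd = ca.shape[0], cb.shape[0], cc.shape[0], cd.shape[0]
    L = la + lb + lc + ld
    out = np.zeros((na, nb, nc, nd))
    for ip in range(aexp.shape[0]):
        a = aexp[ip]
        for jp in range(bexp.shape[0]):
            b = bexp[jp]
            p = a + b
            P = (a * A + b * B) / p
            Exab = e_table(la, lb, a, b, A[0] - B[0])
            Eyab = e_table(la, lb, a, b, A[1] - B[1])
            Ezab = e_table(la, lb, a, b, A[2] - B[2])
            cab = acoef[ip] * bcoef[jp]
            for kp in range(cexp.shape[0]):
                c = cexp[kp]
                for lp in range(dexp.shape[0]):
                    d = dexp[lp]
                    q = c + d
                    Q = (c * C + d * D) / q
                    Excd = e_table(lc, ld, c, d, C[0] - D[0])
                    Eycd = e_table(lc, ld, c, d, C[1] - D[1])
                    Ezcd = e_table(lc, ld, c, d, C[2] - D[2])
                    alpha = p * q / (p + q)
                    R = r_tensor(L, alpha, P[0] - Q[0], P[1] - Q[1],
                                 P[2] - Q[2])
                    pref = (cab * ccoef[kp] * dcoef[lp]
                            * 2.0 * math.pi ** 2.5
                            / (p * q * math.sqrt(p + q)))
                    for ia in range(na):
                        ax_, ay_, az_ = ca[ia, 0], ca[ia, 1], ca[ia, 2]
                        nai = comp_norm(a, ax_, ay_, az_)
                        for ib in range(nb):
                            bx_, by_, bz_ = cb[ib, 0], cb[ib, 1], cb[ib, 2]
                            nbj = comp_norm(b, bx_, by_, bz_)
                            for ic in range(nc):
                                cx_, cy_, cz_ = cc[ic, 0], cc[ic, 1], cc[ic, 2]
                                nck = comp_norm(c, cx_, cy_, cz_)
                                for id_ in range(nd):
                                    dx_, dy_, dz_ = (cd[id_, 0], cd[id_, 1],
                                                     cd[id_, 2])
                                    ndl = comp_norm(d, dx_, dy_, dz_)
                                    acc = 0.0
                                    for t in range(ax_ + bx_ + 1):
                                        e1 = Exab[ax_, bx_, t]
                                        for u in range(ay_ + by_ + 1):
                                            e2 = e1 * Eyab[ay_, by_, u]
                                            for v in range(az_ + bz_ + 1):
                                                e3 = e2 * Ezab[az_, bz_, v]
                                                for tt in range(cx_ + dx_ + 1):
                                                    f1 = e3 * Excd[cx_, dx_, tt]
                                                    for uu in range(cy_ + dy_ + 1):
                                                        f2 = f1 * Eycd[cy_, dy_, uu]
                                                        for vv in range(cz_ + dz_ + 1):
                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                            acc += (sgn * f2
                                                                    * Ezcd[cz_, dz_, vv]
                                                                    * R[t + tt, u + uu, v + vv])
                                    out[ia, ib, ic, id_] += (
                                        pref * nai * nbj * nck * ndl * acc)
    return out
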