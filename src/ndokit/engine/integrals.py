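"""Molecular integrals over contracted Cartesian Gaussians.

McMurchie-Davidson scheme: products of Gaussians are expanded in Hermite
Gaussians (E coefficients); Coulomb-type integrals reduce to the Hermite
Coulomb tensor R built from the Boys function.  Everything is compiled with
numba; shells arrive as the flat arrays produced by BasisSet.flatten().

Supported angular momenta: s, p, d (Cartesian 6d).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .basis import CART_COMPONENTS, component_norm_factors

# flat component tables indexed by l: comp_x[l][m] etc.
_MAXL = 2
_NCOMP = np.array([1, 3, 6], dtype=np.int64)
_COMP = np.zeros((_MAXL + 1, 6, 3), dtype=np.int64)
for _l, comps in CART_COMPONENTS.items():
    for _m, c in enumerate(comps):
        _COMP[_l, _m] = c
_CNORM = np.zeros((_MAXL + 1, 6))
for _l in range(_MAXL + 1):
    f = component_norm_factors(_l)
    _CNORM[_l, :len(f)] = f


@njit(cache=True)
def _boys(mmax, x, F):
    """Boys function F_m(x) for m = 0..mmax."""
    if x < 1e-14:
        for m in range(mmax + 1):
            F[m] = 1.0 / (2.0 * m + 1.0)
        return
    if x < 35.0:
        # series for the highest order, then downward recursion
        m = mmax
        term = 1.0 / (2.0 * m + 1.0)
        s = term
        k = 1
        while True:
            term *= 2.0 * x / (2.0 * m + 2.0 * k + 1.0)
            s += term
            if term < 1e-17 * s or k > 200:
                break
            k += 1
        ex = np.exp(-x)
        F[mmax] = s * ex
        for mm in range(mmax, 0, -1):
            F[mm - 1] = (2.0 * x * F[mm] + ex) / (2.0 * mm - 1.0)
    else:
        F[0] = 0.5 * np.sqrt(np.pi / x)
        for m in range(1, mmax + 1):
            F[m] = F[m - 1] * (2.0 * m - 1.0) / (2.0 * x)


@njit(cache=True)
def _e_tables(la, lb, a, b, AB, E):
    """Hermite expansion coefficients for the three dimensions.

    E has shape (3, la+1, lb+1, la+lb+1); the Gaussian-product prefactor
    exp(-mu*AB_d^2) is folded into dimension d's E[0,0,0].
    """
    p = a + b
    mu = a * b / p
    o2p = 0.5 / p
    for d in range(3):
        PA = -b / p * AB[d]
        PB = a / p * AB[d]
        E[d, :, :, :] = 0.0
        E[d, 0, 0, 0] = np.exp(-mu * AB[d] * AB[d])
        for i in range(la):
            for t in range(i + 2):
                v = PA * E[d, i, 0, t]
                if t > 0:
                    v += o2p * E[d, i, 0, t - 1]
                if t + 1 <= i:
                    v += (t + 1.0) * E[d, i, 0, t + 1]
                E[d, i + 1, 0, t] = v
        for i in range(la + 1):
            for j in range(lb):
                for t in range(i + j + 2):
                    v = PB * E[d, i, j, t]
                    if t > 0:
                        v += o2p * E[d, i, j, t - 1]
                    if t + 1 <= i + j:
                        v += (t + 1.0) * E[d, i, j, t + 1]
                    E[d, i, j + 1, t] = v


@njit(cache=True)
def _r_tensor(L, alpha, PQ, R):
    """Hermite Coulomb tensor R_{tuv} (n=0 slice) for total order L.

    R has shape (L+1, L+1, L+1, L+1): [n, t, u, v].  Built by the standard
    downward-in-n recursion from R^n_{000} = (-2 alpha)^n F_n(alpha |PQ|^2).
    """
    x2 = alpha * (PQ[0] * PQ[0] + PQ[1] * PQ[1] + PQ[2] * PQ[2])
    F = np.empty(L + 1)
    _boys(L, x2, F)
    R[:, :, :, :] = 0.0
    fac = 1.0
    for n in range(L + 1):
        R[n, 0, 0, 0] = fac * F[n]
        fac *= -2.0 * alpha
    for n in range(L - 1, -1, -1):
        for t in range(L - n + 1):
            for u in range(L - n - t + 1):
                for v in range(L - n - t - u + 1):
                    if t + u + v == 0:
                        continue
                    if t > 0:
                        val = PQ[0] * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1.0) * R[n + 1, t - 2, u, v]
                        R[n, t, u, v] = val
                    elif u > 0:
                        val = PQ[1] * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1.0) * R[n + 1, t, u - 2, v]
                        R[n, t, u, v] = val
                    else:
                        val = PQ[2] * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1.0) * R[n + 1, t, u, v - 2]
                        R[n, t, u, v] = val


@njit(cache=True)
def _overlap_kinetic_kernel(shell_l, first_ao, ptr, exps, coefs, origins,
                            comp, ncomp, cnorm, nao):
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    nsh = len(shell_l)
    E = np.empty((3, _MAXL + 2, _MAXL + 4, 2 * _MAXL + 6))
    for ish in range(nsh):
        la = shell_l[ish]
        A = origins[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            B = origins[jsh]
            AB = A - B
            na, nb = ncomp[la], ncomp[lb]
            blockS = np.zeros((na, nb))
            blockT = np.zeros((na, nb))
            for ip in range(ptr[ish], ptr[ish + 1]):
                a = exps[ip]
                ca = coefs[ip]
                for jp in range(ptr[jsh], ptr[jsh + 1]):
                    b = exps[jp]
                    cb = coefs[jp]
                    p = a + b
                    _e_tables(la, lb + 2, a, b, AB, E)
                    pref = ca * cb * (np.pi / p) ** 1.5
                    for ma in range(na):
                        ia0, ja0, ka0 = comp[la, ma]
                        for mb in range(nb):
                            ib0, jb0, kb0 = comp[lb, mb]
                            # 1D overlaps and kinetic terms per dimension
                            sx = E[0, ia0, ib0, 0]
                            sy = E[1, ja0, jb0, 0]
                            sz = E[2, ka0, kb0, 0]
                            # T_1d = -2b^2 S(i,j+2) + b(2j+1) S(i,j)
                            #        - j(j-1)/2 S(i,j-2)
                            tx = -2.0 * b * b * E[0, ia0, ib0 + 2, 0] \
                                + b * (2.0 * ib0 + 1.0) * sx
                            if ib0 >= 2:
                                tx -= 0.5 * ib0 * (ib0 - 1.0) * E[0, ia0, ib0 - 2, 0]
                            ty = -2.0 * b * b * E[1, ja0, jb0 + 2, 0] \
                                + b * (2.0 * jb0 + 1.0) * sy
                            if jb0 >= 2:
                                ty -= 0.5 * jb0 * (jb0 - 1.0) * E[1, ja0, jb0 - 2, 0]
                            tz = -2.0 * b * b * E[2, ka0, kb0 + 2, 0] \
                                + b * (2.0 * kb0 + 1.0) * sz
                            if kb0 >= 2:
                                tz -= 0.5 * kb0 * (kb0 - 1.0) * E[2, ka0, kb0 - 2, 0]
                            cn = cnorm[la, ma] * cnorm[lb, mb]
                            blockS[ma, mb] += pref * cn * sx * sy * sz
                            blockT[ma, mb] += pref * cn * (
                                tx * sy * sz + sx * ty * sz + sx * sy * tz)
            for ma in range(na):
                for mb in range(nb):
                    mu = first_ao[ish] + ma
                    nu = first_ao[jsh] + mb
                    S[mu, nu] = blockS[ma, mb]
                    S[nu, mu] = blockS[ma, mb]
                    T[mu, nu] = blockT[ma, mb]
                    T[nu, mu] = blockT[ma, mb]
    return S, T


@njit(cache=True)
def _nuclear_kernel(shell_l, first_ao, ptr, exps, coefs, origins,
                    comp, ncomp, cnorm, nao, charges, centers):
    V = np.zeros((nao, nao))
    nsh = len(shell_l)
    E = np.empty((3, _MAXL + 2, _MAXL + 2, 2 * _MAXL + 4))
    L = 2 * _MAXL
    R = np.empty((L + 1, L + 1, L + 1, L + 1))
    ncharge = len(charges)
    for ish in range(nsh):
        la = shell_l[ish]
        A = origins[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            B = origins[jsh]
            AB = A - B
            na, nb = ncomp[la], ncomp[lb]
            block = np.zeros((na, nb))
            Ltot = la + lb
            for ip in range(ptr[ish], ptr[ish + 1]):
                a = exps[ip]
                ca = coefs[ip]
                for jp in range(ptr[jsh], ptr[jsh + 1]):
                    b = exps[jp]
                    cb = coefs[jp]
                    p = a + b
                    P = (a * A + b * B) / p
                    _e_tables(la, lb, a, b, AB, E)
                    pref = ca * cb * 2.0 * np.pi / p
                    for ic in range(ncharge):
                        PQ = P - centers[ic]
                        _r_tensor(Ltot, p, PQ, R)
                        q = -charges[ic] * pref
                        for ma in range(na):
                            ia0, ja0, ka0 = comp[la, ma]
                            for mb in range(nb):
                                ib0, jb0, kb0 = comp[lb, mb]
                                acc = 0.0
                                for t in range(ia0 + ib0 + 1):
                                    et = E[0, ia0, ib0, t]
                                    for u in range(ja0 + jb0 + 1):
                                        eu = E[1, ja0, jb0, u]
                                        for v in range(ka0 + kb0 + 1):
                                            acc += et * eu * \
                                                E[2, ka0, kb0, v] * R[0, t, u, v]
                                block[ma, mb] += q * acc * \
                                    cnorm[la, ma] * cnorm[lb, mb]
            for ma in range(na):
                for mb in range(nb):
                    mu = first_ao[ish] + ma
                    nu = first_ao[jsh] + mb
                    V[mu, nu] = block[ma, mb]
                    V[nu, mu] = block[ma, mb]
    return V


@njit(cache=True)
def _pair_data(shell_l, ptr, exps, coefs, origins, thresh):
    """Precompute significant primitive-pair data for all shell pairs.

    Returns flat arrays describing, for every ordered shell pair (i>=j),
    its primitive pairs: total exponent p, center P, combined coefficient
    (including the Gaussian product prefactor), and E tables.
    """
    nsh = len(shell_l)
    npair = nsh * (nsh + 1) // 2
    # count primitive pairs first
    pp_ptr = np.zeros(npair + 1, dtype=np.int64)
    idx = 0
    for ish in range(nsh):
        for jsh in range(ish + 1):
            n = (ptr[ish + 1] - ptr[ish]) * (ptr[jsh + 1] - ptr[jsh])
            pp_ptr[idx + 1] = pp_ptr[idx] + n
            idx += 1
    ntot = pp_ptr[npair]
    pp_p = np.empty(ntot)
    pp_P = np.empty((ntot, 3))
    pp_c = np.empty(ntot)
    maxE = 3 * (_MAXL + 1) * (_MAXL + 1) * (2 * _MAXL + 1)
    pp_E = np.empty((ntot, maxE))
    pair_i = np.empty(npair, dtype=np.int64)
    pair_j = np.empty(npair, dtype=np.int64)
    pp_n = np.zeros(npair, dtype=np.int64)
    E = np.empty((3, _MAXL + 2, _MAXL + 2, 2 * _MAXL + 4))
    idx = 0
    for ish in range(nsh):
        la = shell_l[ish]
        A = origins[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            B = origins[jsh]
            AB = A - B
            pair_i[idx] = ish
            pair_j[idx] = jsh
            k = pp_ptr[idx]
            for ip in range(ptr[ish], ptr[ish + 1]):
                a = exps[ip]
                for jp in range(ptr[jsh], ptr[jsh + 1]):
                    b = exps[jp]
                    p = a + b
                    mu = a * b / p
                    r2 = AB[0] * AB[0] + AB[1] * AB[1] + AB[2] * AB[2]
                    cc = coefs[ip] * coefs[jp]
                    if abs(cc) * np.exp(-mu * r2) < thresh:
                        continue
                    _e_tables(la, lb, a, b, AB, E)
                    pp_p[k] = p
                    pp_P[k] = (a * A + b * B) / p
                    pp_c[k] = cc
                    # flatten E (prefactor exp(-mu AB^2) is inside E)
                    m = 0
                    for d in range(3):
                        for i in range(_MAXL + 1):
                            for j in range(_MAXL + 1):
                                for t in range(2 * _MAXL + 1):
                                    if i <= la and j <= lb and t <= la + lb:
                                        pp_E[k, m] = E[d, i, j, t]
                                    else:
                                        pp_E[k, m] = 0.0
                                    m += 1
                    k += 1
            pp_n[idx] = k - pp_ptr[idx]
            idx += 1
    return pair_i, pair_j, pp_ptr, pp_n, pp_p, pp_P, pp_c, pp_E


@njit(inline="always")
def _Eget(pp_E, k, d, i, j, t):
    n2 = (_MAXL + 1) * (2 * _MAXL + 1)
    n3 = (_MAXL + 1) * n2
    return pp_E[k, d * n3 + i * n2 + j * (2 * _MAXL + 1) + t]


@njit(cache=True)
def _eri_kernel(shell_l, first_ao, ptr, exps, coefs, origins,
                comp, ncomp, cnorm, nao, thresh):
    pair_i, pair_j, pp_ptr, pp_n, pp_p, pp_P, pp_c, pp_E = _pair_data(
        shell_l, ptr, exps, coefs, origins, 1e-16)
    npair = len(pair_i)
    eri = np.zeros((nao, nao, nao, nao))
    Lmax = 4 * _MAXL
    R = np.empty((Lmax + 1, Lmax + 1, Lmax + 1, Lmax + 1))

    # Schwarz bounds per shell pair
    Q = np.zeros(npair)
    for sp in range(npair):
        ish, jsh = pair_i[sp], pair_j[sp]
        la, lb = shell_l[ish], shell_l[jsh]
        Ltot = 2 * (la + lb)
        mx = 0.0
        for k1 in range(pp_ptr[sp], pp_ptr[sp] + pp_n[sp]):
            p = pp_p[k1]
            for k2 in range(pp_ptr[sp], pp_ptr[sp] + pp_n[sp]):
                q = pp_p[k2]
                alpha = p * q / (p + q)
                PQ = pp_P[k1] - pp_P[k2]
                _r_tensor(Ltot, alpha, PQ, R)
                pref = pp_c[k1] * pp_c[k2] * 2.0 * np.pi ** 2.5 / \
                    (p * q * np.sqrt(p + q))
                for ma in range(ncomp[la]):
                    ia0, ja0, ka0 = comp[la, ma]
                    for mb in range(ncomp[lb]):
                        ib0, jb0, kb0 = comp[lb, mb]
                        acc = 0.0
                        for t in range(ia0 + ib0 + 1):
                            for u in range(ja0 + jb0 + 1):
                                for v in range(ka0 + kb0 + 1):
                                    e1 = _Eget(pp_E, k1, 0, ia0, ib0, t) * \
                                        _Eget(pp_E, k1, 1, ja0, jb0, u) * \
                                        _Eget(pp_E, k1, 2, ka0, kb0, v)
                                    if e1 == 0.0:
                                        continue
                                    for t2 in range(ia0 + ib0 + 1):
                                        for u2 in range(ja0 + jb0 + 1):
                                            for v2 in range(ka0 + kb0 + 1):
                                                e2 = _Eget(pp_E, k2, 0, ia0, ib0, t2) * \
                                                    _Eget(pp_E, k2, 1, ja0, jb0, u2) * \
                                                    _Eget(pp_E, k2, 2, ka0, kb0, v2)
                                                sgn = 1.0 if (t2 + u2 + v2) % 2 == 0 else -1.0
                                                acc += e1 * e2 * sgn * \
                                                    R[0, t + t2, u + u2, v + v2]
                        val = abs(pref * acc) * (cnorm[la, ma] * cnorm[lb, mb]) ** 2
                        if val > mx:
                            mx = val
        Q[sp] = np.sqrt(mx)

    for sp1 in range(npair):
        ish, jsh = pair_i[sp1], pair_j[sp1]
        la, lb = shell_l[ish], shell_l[jsh]
        na, nb = ncomp[la], ncomp[lb]
        for sp2 in range(sp1 + 1):
            if Q[sp1] * Q[sp2] < thresh:
                continue
            ksh, lsh = pair_i[sp2], pair_j[sp2]
            lc, ld = shell_l[ksh], shell_l[lsh]
            nc, nd = ncomp[lc], ncomp[ld]
            Ltot = la + lb + lc + ld
            block = np.zeros((na, nb, nc, nd))
            for k1 in range(pp_ptr[sp1], pp_ptr[sp1] + pp_n[sp1]):
                p = pp_p[k1]
                c1 = pp_c[k1]
                for k2 in range(pp_ptr[sp2], pp_ptr[sp2] + pp_n[sp2]):
                    q = pp_p[k2]
                    alpha = p * q / (p + q)
                    PQ = pp_P[k1] - pp_P[k2]
                    _r_tensor(Ltot, alpha, PQ, R)
                    pref = c1 * pp_c[k2] * 2.0 * np.pi ** 2.5 / \
                        (p * q * np.sqrt(p + q))
                    for ma in range(na):
                        ia0, ja0, ka0 = comp[la, ma]
                        for mb in range(nb):
                            ib0, jb0, kb0 = comp[lb, mb]
                            for mc in range(nc):
                                ic0, jc0, kc0 = comp[lc, mc]
                                for md in range(nd):
                                    id0, jd0, kd0 = comp[ld, md]
                                    acc = 0.0
                                    for t in range(ia0 + ib0 + 1):
                                        for u in range(ja0 + jb0 + 1):
                                            for v in range(ka0 + kb0 + 1):
                                                e1 = _Eget(pp_E, k1, 0, ia0, ib0, t) * \
                                                    _Eget(pp_E, k1, 1, ja0, jb0, u) * \
                                                    _Eget(pp_E, k1, 2, ka0, kb0, v)
                                                if e1 == 0.0:
                                                    continue
                                                for t2 in range(ic0 + id0 + 1):
                                                    for u2 in range(jc0 + jd0 + 1):
                                                        for v2 in range(kc0 + kd0 + 1):
                                                            e2 = _Eget(pp_E, k2, 0, ic0, id0, t2) * \
                                                                _Eget(pp_E, k2, 1, jc0, jd0, u2) * \
                                                                _Eget(pp_E, k2, 2, kc0, kd0, v2)
                                                            sgn = 1.0 if (t2 + u2 + v2) % 2 == 0 else -1.0
                                                            acc += e1 * e2 * sgn * \
                                                                R[0, t + t2, u + u2, v + v2]
                                    block[ma, mb, mc, md] += pref * acc * \
                                        cnorm[la, ma] * cnorm[lb, mb] * \
                                        cnorm[lc, mc] * cnorm[ld, md]
            for ma in range(na):
                mu = first_ao[ish] + ma
                for mb in range(nb):
                    nu = first_ao[jsh] + mb
                    for mc in range(nc):
                        lam = first_ao[ksh] + mc
                        for md in range(nd):
                            sig = first_ao[lsh] + md
                            v = block[ma, mb, mc, md]
                            eri[mu, nu, lam, sig] = v
                            eri[nu, mu, lam, sig] = v
                            eri[mu, nu, sig, lam] = v
                            eri[nu, mu, sig, lam] = v
                            eri[lam, sig, mu, nu] = v
                            eri[sig, lam, mu, nu] = v
                            eri[lam, sig, nu, mu] = v
                            eri[sig, lam, nu, mu] = v
    return eri


@njit(cache=True)
def _ao_values_kernel(shell_l, first_ao, ptr, exps, coefs, origins,
                      comp, ncomp, cnorm, nao, points, deriv):
    npts = len(points)
    val = np.zeros((npts, nao))
    grad = np.zeros((npts, nao, 3)) if deriv >= 1 else np.zeros((1, 1, 3))
    # hess components xx,yy,zz,xy,xz,yz
    hess = np.zeros((npts, nao, 6)) if deriv >= 2 else np.zeros((1, 1, 6))
    nsh = len(shell_l)
    f = np.empty((3, 3))   # value, 1st, 2nd derivative factors per dim
    for ipt in range(npts):
        x, y, z = points[ipt]
        for ish in range(nsh):
            la = shell_l[ish]
            A = origins[ish]
            dx, dy, dz = x - A[0], y - A[1], z - A[2]
            r2 = dx * dx + dy * dy + dz * dz
            for ip in range(ptr[ish], ptr[ish + 1]):
                a = exps[ip]
                ar2 = a * r2
                if ar2 > 40.0:
                    continue
                g = coefs[ip] * np.exp(-ar2)
                for ma in range(ncomp[la]):
                    i0, j0, k0 = comp[la, ma]
                    cn = cnorm[la, ma] * g
                    for d in range(3):
                        if d == 0:
                            t, n = dx, i0
                        elif d == 1:
                            t, n = dy, j0
                        else:
                            t, n = dz, k0
                        tn = t ** n if n > 0 else 1.0
                        f[d, 0] = tn
                        if deriv >= 1:
                            d1 = -2.0 * a * t * tn
                            if n > 0:
                                d1 += n * t ** (n - 1)
                            f[d, 1] = d1
                        if deriv >= 2:
                            d2 = (4.0 * a * a * t * t - 2.0 * a *
                                  (2.0 * n + 1.0)) * tn
                            if n > 1:
                                d2 += n * (n - 1.0) * t ** (n - 2)
                            f[d, 2] = d2
                    mu = first_ao[ish] + ma
                    val[ipt, mu] += cn * f[0, 0] * f[1, 0] * f[2, 0]
                    if deriv >= 1:
                        grad[ipt, mu, 0] += cn * f[0, 1] * f[1, 0] * f[2, 0]
                        grad[ipt, mu, 1] += cn * f[0, 0] * f[1, 1] * f[2, 0]
                        grad[ipt, mu, 2] += cn * f[0, 0] * f[1, 0] * f[2, 1]
                    if deriv >= 2:
                        hess[ipt, mu, 0] += cn * f[0, 2] * f[1, 0] * f[2, 0]
                        hess[ipt, mu, 1] += cn * f[0, 0] * f[1, 2] * f[2, 0]
                        hess[ipt, mu, 2] += cn * f[0, 0] * f[1, 0] * f[2, 2]
                        hess[ipt, mu, 3] += cn * f[0, 1] * f[1, 1] * f[2, 0]
                        hess[ipt, mu, 4] += cn * f[0, 1] * f[1, 0] * f[2, 1]
                        hess[ipt, mu, 5] += cn * f[0, 0] * f[1, 1] * f[2, 1]
    return val, grad, hess


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def _args(basis):
    shell_l, shell_atom, first, ptr, exps, coefs, origins = basis.flatten()
    return (shell_l, first, ptr, exps, coefs, origins,
            _COMP, _NCOMP, _CNORM, basis.n_basis)


def overlap_kinetic(basis):
    """Overlap and kinetic-energy matrices (S, T)."""
    return _overlap_kinetic_kernel(*_args(basis))


def overlap(basis):
    return overlap_kinetic(basis)[0]


def nuclear_attraction(basis, charges=None, centers=None):
    """Electron-nuclear attraction matrix (negative-definite part of Hcore).

    With explicit charges/centers this doubles as the interaction with an
    arbitrary set of point charges.
    """
    if charges is None:
        charges = basis.charges
        centers = basis.coords
    charges = np.asarray(charges, dtype=float)
    centers = np.ascontiguousarray(np.asarray(centers, dtype=float).reshape(-1, 3))
    return _nuclear_kernel(*_args(basis), charges, centers)


def eri(basis, thresh=1e-12):
    """Full (mu nu | lambda sigma) tensor in chemists' notation."""
    return _eri_kernel(*_args(basis), thresh)


def ao_values(basis, points, deriv=0):
    """AO values (and optionally gradients / second derivatives) on points.

    Returns val (npts, nao); with deriv>=1 also grad (npts, nao, 3); with
    deriv>=2 also the six second derivatives (xx, yy, zz, xy, xz, yz).
    """
    points = np.ascontiguousarray(np.asarray(points, float).reshape(-1, 3))
    val, grad, hess = _ao_values_kernel(*_args(basis), points, deriv)
    if deriv == 0:
        return val
    if deriv == 1:
        return val, grad
    return val, grad, hess


def nuclear_repulsion(charges, coords):
    charges = np.asarray(charges, float)
    coords = np.asarray(coords, float)
    e = 0.0
    n = len(charges)
    for i in range(n):
        for j in range(i):
            e += charges[i] * charges[j] / np.linalg.norm(coords[i] - coords[j])
    return e
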