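"""Analytic nuclear gradients for the restricted HF/KS engine.

Derivatives of Gaussian integrals are assembled with the shifted-angular-
momentum rule d/dA_x = 2a*(l_x+1) - l_x*(l_x-1) applied inside the
McMurchie-Davidson primitive loops.  The xc contribution neglects the
derivatives of the quadrature weights (standard practice at reasonable
grid densities).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import integrals as ints
from .integrals import _MAXL, _args, _e_tables, _r_tensor


@njit(cache=True)
def _grad_s_t_kernel(shell_l, first_ao, ptr, exps, coefs, origins,
                     comp, ncomp, cnorm, nao, shell_atom, natom, W, P):
    """-sum W dS/dR + sum P dT/dR, bra-side derivative over ordered pairs."""
    grad = np.zeros((natom, 3))
    nsh = len(shell_l)
    E = np.empty((3, _MAXL + 3, _MAXL + 5, 2 * _MAXL + 8))
    for ish in range(nsh):
        la = shell_l[ish]
        A = origins[ish]
        atomA = shell_atom[ish]
        for jsh in range(nsh):
            lb = shell_l[jsh]
            B = origins[jsh]
            AB = A - B
            na, nb = ncomp[la], ncomp[lb]
            for ip in range(ptr[ish], ptr[ish + 1]):
                a = exps[ip]
                ca = coefs[ip]
                for jp in range(ptr[jsh], ptr[jsh + 1]):
                    b = exps[jp]
                    cb = coefs[jp]
                    p = a + b
                    _e_tables(la + 1, lb + 2, a, b, AB, E)
                    pref = ca * cb * (np.pi / p) ** 1.5
                    for ma in range(na):
                        ii = comp[la, ma]
                        for mb in range(nb):
                            jj = comp[lb, mb]
                            mu = first_ao[ish] + ma
                            nu = first_ao[jsh] + mb
                            cn = cnorm[la, ma] * cnorm[lb, mb] * pref
                            wmn = W[mu, nu]
                            pmn = P[mu, nu]
                            for d in range(3):
                                i1 = ii[d]
                                # 1D overlap rows for the two remaining dims
                                o1 = 1.0
                                t1 = np.zeros(3)
                                for dd in range(3):
                                    iA = ii[dd]
                                    iB = jj[dd]
                                    s0 = E[dd, iA, iB, 0]
                                    tt = -2.0 * b * b * E[dd, iA, iB + 2, 0] \
                                        + b * (2.0 * iB + 1.0) * s0
                                    if iB >= 2:
                                        tt -= 0.5 * iB * (iB - 1.0) * \
                                            E[dd, iA, iB - 2, 0]
                                    t1[dd] = tt
                                # derivative of the 1D overlap/kinetic in dim d
                                dS1 = 2.0 * a * E[d, i1 + 1, jj[d], 0]
                                if i1 > 0:
                                    dS1 -= i1 * E[d, i1 - 1, jj[d], 0]
                                iB = jj[d]
                                dT1 = 2.0 * a * (
                                    -2.0 * b * b * E[d, i1 + 1, iB + 2, 0]
                                    + b * (2.0 * iB + 1.0) * E[d, i1 + 1, iB, 0]
                                    - (0.5 * iB * (iB - 1.0) * E[d, i1 + 1, iB - 2, 0]
                                       if iB >= 2 else 0.0))
                                if i1 > 0:
                                    dT1 -= i1 * (
                                        -2.0 * b * b * E[d, i1 - 1, iB + 2, 0]
                                        + b * (2.0 * iB + 1.0) * E[d, i1 - 1, iB, 0]
                                        - (0.5 * iB * (iB - 1.0) * E[d, i1 - 1, iB - 2, 0]
                                           if iB >= 2 else 0.0))
                                s_rest = 1.0
                                dOther = 0.0
                                for dd in range(3):
                                    if dd != d:
                                        s_rest *= E[dd, ii[dd], jj[dd], 0]
                                # dS3 = dS1 * prod others ; dT3 = sum rule
                                dS3 = dS1 * s_rest
                                dT3 = dT1 * s_rest
                                for dd in range(3):
                                    if dd == d:
                                        continue
                                    oth = 1.0
                                    for d3 in range(3):
                                        if d3 != d and d3 != dd:
                                            oth *= E[d3, ii[d3], jj[d3], 0]
                                    dT3 += t1[dd] * dS1 * oth
                                contrib = cn * (pmn * dT3 - wmn * dS3)
                                grad[atomA, d] += contrib
                                # ket derivative by translational invariance
                                grad[shell_atom[jsh], d] -= contrib
    return grad


@njit(cache=True)
def _grad_v_kernel(shell_l, first_ao, ptr, exps, coefs, origins,
                   comp, ncomp, cnorm, nao, shell_atom, natom, P,
                   charges, centers, center_atom):
    """P-contracted nuclear-attraction gradient: bra derivative (ordered
    pairs) plus the Hellmann-Feynman force on each charge center."""
    grad = np.zeros((natom, 3))
    nsh = len(shell_l)
    E = np.empty((3, _MAXL + 3, _MAXL + 3, 2 * _MAXL + 6))
    Lmax = 2 * _MAXL + 2
    R = np.empty((Lmax + 1, Lmax + 1, Lmax + 1, Lmax + 1))
    ncharge = len(charges)
    for ish in range(nsh):
        la = shell_l[ish]
        A = origins[ish]
        atomA = shell_atom[ish]
        for jsh in range(nsh):
            lb = shell_l[jsh]
            B = origins[jsh]
            AB = A - B
            na, nb = ncomp[la], ncomp[lb]
            Ltot = la + lb + 1
            for ip in range(ptr[ish], ptr[ish + 1]):
                a = exps[ip]
                ca = coefs[ip]
                for jp in range(ptr[jsh], ptr[jsh + 1]):
                    b = exps[jp]
                    cb = coefs[jp]
                    p = a + b
                    Pc = (a * A + b * B) / p
                    _e_tables(la + 1, lb, a, b, AB, E)
                    pref = ca * cb * 2.0 * np.pi / p
                    for ic in range(ncharge):
                        PQ = Pc - centers[ic]
                        _r_tensor(Ltot, p, PQ, R)
                        q = -charges[ic] * pref
                        atomC = center_atom[ic]
                        for ma in range(na):
                            ii = comp[la, ma]
                            for mb in range(nb):
                                jj = comp[lb, mb]
                                mu = first_ao[ish] + ma
                                nu = first_ao[jsh] + mb
                                w = q * cnorm[la, ma] * cnorm[lb, mb] * P[mu, nu]
                                if w == 0.0:
                                    continue
                                for d in range(3):
                                    # bra-derivative term
                                    accp = 0.0
                                    accm = 0.0
                                    i1 = ii[d]
                                    for t in range(ii[0] + jj[0] + 2):
                                        for u in range(ii[1] + jj[1] + 2):
                                            for v in range(ii[2] + jj[2] + 2):
                                                if d == 0:
                                                    e_hi = E[0, i1 + 1, jj[0], t] if t <= i1 + 1 + jj[0] else 0.0
                                                    e_lo = E[0, i1 - 1, jj[0], t] if (i1 > 0 and t <= i1 - 1 + jj[0]) else 0.0
                                                    ey = E[1, ii[1], jj[1], u] if u <= ii[1] + jj[1] else 0.0
                                                    ez = E[2, ii[2], jj[2], v] if v <= ii[2] + jj[2] else 0.0
                                                    accp += e_hi * ey * ez * R[0, t, u, v]
                                                    accm += e_lo * ey * ez * R[0, t, u, v]
                                                elif d == 1:
                                                    ex = E[0, ii[0], jj[0], t] if t <= ii[0] + jj[0] else 0.0
                                                    e_hi = E[1, i1 + 1, jj[1], u] if u <= i1 + 1 + jj[1] else 0.0
                                                    e_lo = E[1, i1 - 1, jj[1], u] if (i1 > 0 and u <= i1 - 1 + jj[1]) else 0.0
                                                    ez = E[2, ii[2], jj[2], v] if v <= ii[2] + jj[2] else 0.0
                                                    accp += ex * e_hi * ez * R[0, t, u, v]
                                                    accm += ex * e_lo * ez * R[0, t, u, v]
                                                else:
                                                    ex = E[0, ii[0], jj[0], t] if t <= ii[0] + jj[0] else 0.0
                                                    ey = E[1, ii[1], jj[1], u] if u <= ii[1] + jj[1] else 0.0
                                                    e_hi = E[2, i1 + 1, jj[2], v] if v <= i1 + 1 + jj[2] else 0.0
                                                    e_lo = E[2, i1 - 1, jj[2], v] if (i1 > 0 and v <= i1 - 1 + jj[2]) else 0.0
                                                    accp += ex * ey * e_hi * R[0, t, u, v]
                                                    accm += ex * ey * e_lo * R[0, t, u, v]
                                    bra = w * (2.0 * a * accp - i1 * accm)
                                    # Hellmann-Feynman force on the charge
                                    acc = 0.0
                                    for t in range(ii[0] + jj[0] + 1):
                                        for u in range(ii[1] + jj[1] + 1):
                                            for v in range(ii[2] + jj[2] + 1):
                                                e3 = E[0, ii[0], jj[0], t] * \
                                                    E[1, ii[1], jj[1], u] * \
                                                    E[2, ii[2], jj[2], v]
                                                if d == 0:
                                                    acc += e3 * R[0, t + 1, u, v]
                                                elif d == 1:
                                                    acc += e3 * R[0, t, u + 1, v]
                                                else:
                                                    acc += e3 * R[0, t, u, v + 1]
                                    hf = w * acc
                                    grad[atomA, d] += bra
                                    grad[atomC, d] -= hf
                                    # ket = -(bra + charge term)
                                    grad[shell_atom[jsh], d] -= bra - hf
    return grad


@njit(cache=True)
def _grad_eri_kernel(shell_l, first_ao, ptr, exps, coefs, origins,
                     comp, ncomp, cnorm, nao, shell_atom, natom,
                     P, cx, thresh):
    """Two-electron gradient contracted with the RHF/hybrid 2-RDM factor."""
    grad = np.zeros((natom, 3))
    nsh = len(shell_l)
    E1 = np.empty((3, _MAXL + 3, _MAXL + 3, 2 * _MAXL + 6))
    E2 = np.empty((3, _MAXL + 3, _MAXL + 3, 2 * _MAXL + 6))
    Lmax = 4 * _MAXL + 1
    R = np.empty((Lmax + 1, Lmax + 1, Lmax + 1, Lmax + 1))
    # shell-pair list
    npair = nsh * (nsh + 1) // 2
    pi = np.empty(npair, dtype=np.int64)
    pj = np.empty(npair, dtype=np.int64)
    k = 0
    for i in range(nsh):
        for j in range(i + 1):
            pi[k] = i
            pj[k] = j
            k += 1
    dint = np.empty((3, 3))  # center (A,B,C) x dimension
    for sp1 in range(npair):
        ish, jsh = pi[sp1], pj[sp1]
        la, lb = shell_l[ish], shell_l[jsh]
        A, B = origins[ish], origins[jsh]
        na, nb = ncomp[la], ncomp[lb]
        for sp2 in range(sp1 + 1):
            ksh, lsh = pi[sp2], pj[sp2]
            lc, ld = shell_l[ksh], shell_l[lsh]
            C, D = origins[ksh], origins[lsh]
            nc, nd = ncomp[lc], ncomp[ld]
            deg = 1.0
            if ish != jsh:
                deg *= 2.0
            if ksh != lsh:
                deg *= 2.0
            if sp1 != sp2:
                deg *= 2.0
            # screen on density magnitude
            dmax = 0.0
            for ma in range(na):
                for mb in range(nb):
                    for mc in range(nc):
                        for md in range(nd):
                            mu = first_ao[ish] + ma
                            nu = first_ao[jsh] + mb
                            lam = first_ao[ksh] + mc
                            sig = first_ao[lsh] + md
                            gfac = 0.5 * P[mu, nu] * P[lam, sig] \
                                - 0.125 * cx * (P[mu, lam] * P[nu, sig]
                                                + P[mu, sig] * P[nu, lam])
                            if abs(gfac) > dmax:
                                dmax = abs(gfac)
            if dmax < thresh:
                continue
            for ipr in range(ptr[ish], ptr[ish + 1]):
                a = exps[ipr]
                for jpr in range(ptr[jsh], ptr[jsh + 1]):
                    b = exps[jpr]
                    p = a + b
                    Pab = (a * A + b * B) / p
                    c1 = coefs[ipr] * coefs[jpr]
                    _e_tables(la + 1, lb + 1, a, b, A - B, E1)
                    for kpr in range(ptr[ksh], ptr[ksh + 1]):
                        c = exps[kpr]
                        for lpr in range(ptr[lsh], ptr[lsh + 1]):
                            d_ = exps[lpr]
                            q = c + d_
                            Qcd = (c * C + d_ * D) / q
                            c2 = coefs[kpr] * coefs[lpr]
                            _e_tables(lc + 1, ld, c, d_, C - D, E2)
                            alpha = p * q / (p + q)
                            Ltot = la + lb + lc + ld + 1
                            _r_tensor(Ltot, alpha, Pab - Qcd, R)
                            pref = c1 * c2 * 2.0 * np.pi ** 2.5 / \
                                (p * q * np.sqrt(p + q))
                            for ma in range(na):
                                ii = comp[la, ma]
                                for mb in range(nb):
                                    jj = comp[lb, mb]
                                    for mc in range(nc):
                                        kk = comp[lc, mc]
                                        for md in range(nd):
                                            ll = comp[ld, md]
                                            mu = first_ao[ish] + ma
                                            nu = first_ao[jsh] + mb
                                            lam = first_ao[ksh] + mc
                                            sig = first_ao[lsh] + md
                                            gfac = 0.5 * P[mu, nu] * P[lam, sig] \
                                                - 0.125 * cx * (P[mu, lam] * P[nu, sig]
                                                                + P[mu, sig] * P[nu, lam])
                                            w = deg * gfac * pref * \
                                                cnorm[la, ma] * cnorm[lb, mb] * \
                                                cnorm[lc, mc] * cnorm[ld, md]
                                            if abs(w) < 1e-14:
                                                continue
                                            _eri_prim_derivs(
                                                E1, E2, R, ii, jj, kk, ll,
                                                a, b, c, dint)
                                            for dd in range(3):
                                                grad[shell_atom[ish], dd] += w * dint[0, dd]
                                                grad[shell_atom[jsh], dd] += w * dint[1, dd]
                                                grad[shell_atom[ksh], dd] += w * dint[2, dd]
                                                grad[shell_atom[lsh], dd] -= w * (
                                                    dint[0, dd] + dint[1, dd] + dint[2, dd])
    return grad


@njit(inline="always")
def _hsum(E1, E2, R, i1, j1, k1, i2, j2, k2, i3, j3, k3, i4, j4, k4):
    """Hermite double sum for one component quartet with given powers."""
    acc = 0.0
    for t in range(i1 + i3 + 1):
        ex1 = E1[0, i1, i3, t]
        if ex1 == 0.0:
            continue
        for u in range(j1 + j3 + 1):
            ey1 = E1[1, j1, j3, u]
            if ey1 == 0.0:
                continue
            for v in range(k1 + k3 + 1):
                ez1 = E1[2, k1, k3, v]
                if ez1 == 0.0:
                    continue
                e1 = ex1 * ey1 * ez1
                for t2 in range(i2 + i4 + 1):
                    ex2 = E2[0, i2, i4, t2]
                    if ex2 == 0.0:
                        continue
                    for u2 in range(j2 + j4 + 1):
                        ey2 = E2[1, j2, j4, u2]
                        if ey2 == 0.0:
                            continue
                        for v2 in range(k2 + k4 + 1):
                            ez2 = E2[2, k2, k4, v2]
                            if ez2 == 0.0:
                                continue
                            sgn = 1.0 if (t2 + u2 + v2) % 2 == 0 else -1.0
                            acc += e1 * sgn * ex2 * ey2 * ez2 * \
                                R[0, t + t2, u + u2, v + v2]
    return acc


@njit(inline="always")
def _eri_prim_derivs(E1, E2, R, ii, jj, kk, ll, a, b, c, dint):
    """d(ab|cd)/d{A,B,C} for one component quartet (one primitive set)."""
    for d in range(3):
        i1 = np.array([ii[0], ii[1], ii[2]])
        i2 = np.array([kk[0], kk[1], kk[2]])
        i3 = np.array([jj[0], jj[1], jj[2]])
        i4 = np.array([ll[0], ll[1], ll[2]])
        # center A: raise/lower ii[d]
        i1[d] += 1
        hi = _hsum(E1, E2, R, i1[0], i1[1], i1[2], i2[0], i2[1], i2[2],
                   i3[0], i3[1], i3[2], i4[0], i4[1], i4[2])
        v = 2.0 * a * hi
        if ii[d] > 0:
            i1[d] -= 2
            lo = _hsum(E1, E2, R, i1[0], i1[1], i1[2], i2[0], i2[1], i2[2],
                       i3[0], i3[1], i3[2], i4[0], i4[1], i4[2])
            v -= ii[d] * lo
            i1[d] += 2
        i1[d] -= 1
        dint[0, d] = v
        # center B: raise/lower jj[d]
        i3[d] += 1
        hi = _hsum(E1, E2, R, i1[0], i1[1], i1[2], i2[0], i2[1], i2[2],
                   i3[0], i3[1], i3[2], i4[0], i4[1], i4[2])
        v = 2.0 * b * hi
        if jj[d] > 0:
            i3[d] -= 2
            lo = _hsum(E1, E2, R, i1[0], i1[1], i1[2], i2[0], i2[1], i2[2],
                       i3[0], i3[1], i3[2], i4[0], i4[1], i4[2])
            v -= jj[d] * lo
            i3[d] += 2
        i3[d] -= 1
        dint[1, d] = v
        # center C: raise/lower kk[d]
        i2[d] += 1
        hi = _hsum(E1, E2, R, i1[0], i1[1], i1[2], i2[0], i2[1], i2[2],
                   i3[0], i3[1], i3[2], i4[0], i4[1], i4[2])
        v = 2.0 * c * hi
        if kk[d] > 0:
            i2[d] -= 2
            lo = _hsum(E1, E2, R, i1[0], i1[1], i1[2], i2[0], i2[1], i2[2],
                       i3[0], i3[1], i3[2], i4[0], i4[1], i4[2])
            v -= kk[d] * lo
            i2[d] += 2
        i2[d] -= 1
        dint[2, d] = v


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def nuclear_gradient(engine, solution):
    """Total-energy nuclear gradient (hartree/bohr) for a converged solution.

    Grid-weight derivatives in the xc term are neglected.
    """
    basis = engine.basis
    natom = len(engine.elements)
    P = solution.density
    Cocc = solution.C[:, solution.occ > 1e-8]
    W = (Cocc * (solution.occ[solution.occ > 1e-8]
                 * solution.eps[solution.occ > 1e-8])) @ Cocc.T
    args = _args(basis)
    shell_atom = np.array([sh.atom for sh in basis.shells], dtype=np.int64)
    g = _grad_s_t_kernel(*args, shell_atom, natom, W, P)
    center_atom = np.arange(natom, dtype=np.int64)
    g += _grad_v_kernel(*args, shell_atom, natom, P,
                        basis.charges, basis.coords, center_atom)
    cx = engine.functional.exact_exchange
    g += _grad_eri_kernel(*args, shell_atom, natom, P, cx, 1e-11)
    g += _nuclear_repulsion_gradient(basis.charges, basis.coords)
    if engine.functional.pieces:
        g += _xc_gradient(engine, P)
    return g


def _nuclear_repulsion_gradient(charges, coords):
    natom = len(charges)
    g = np.zeros((natom, 3))
    for i in range(natom):
        for j in range(natom):
            if i == j:
                continue
            rij = coords[i] - coords[j]
            g[i] -= charges[i] * charges[j] * rij / np.linalg.norm(rij) ** 3
    return g


def _xc_gradient(engine, P, chunk=20000):
    """Grid xc gradient; needs AO first (LDA) / second (GGA) derivatives."""
    g_obj, _, _ = engine._grid_ao()
    func = engine.functional
    natom = len(engine.elements)
    atom_of = engine.basis.atom_of_basis
    grad = np.zeros((natom, 3))
    pts, wts = g_obj.points, g_obj.weights
    needs_sigma = func.needs_sigma
    for lo in range(0, len(pts), chunk):
        hi = min(lo + chunk, len(pts))
        p, w = pts[lo:hi], wts[lo:hi]
        if needs_sigma:
            ao, aog, aoh = ints.ao_values(engine.basis, p, deriv=2)
        else:
            ao, aog = ints.ao_values(engine.basis, p, deriv=1)
            aoh = None
        tmp = ao @ P              # (np, nao)
        rho = np.einsum("pi,pi->p", tmp, ao)
        np.clip(rho, 0.0, None, out=rho)
        if needs_sigma:
            grho = 2.0 * np.einsum("pid,pi->pd", aog, tmp)
            sigma = np.einsum("pd,pd->p", grho, grho)
            e, vr, vs = func.e_and_potential(rho, sigma)
        else:
            e, vr, vs = func.e_and_potential(rho)
        # drho/dR_A = -2 sum_{mu in A} dchi_mu (P ao)_mu
        wv = w * vr
        contrib = -2.0 * np.einsum("p,pid,pi->id", wv, aog, tmp)
        np.add.at(grad, atom_of, contrib)
        if needs_sigma:
            # dsigma/dR_A = 2 grho . d(grho)/dR_A with
            # d(grho)_e/dRA_d = -2 sum_{mu in A} [hess_mu(d,e) (P ao)_mu
            #                                     + dchi_mu,d (P aog_e)_mu]
            Pg = np.einsum("ij,pje->pie", P, aog)
            wvs = 2.0 * w * vs
            hmap = {(0, 0): 0, (1, 1): 1, (2, 2): 2,
                    (0, 1): 3, (1, 0): 3, (0, 2): 4, (2, 0): 4,
                    (1, 2): 5, (2, 1): 5}
            for dcomp in range(3):
                tot = np.zeros(ao.shape[1])
                for ecomp in range(3):
                    h = aoh[:, :, hmap[(dcomp, ecomp)]]
                    t1 = np.einsum("p,pi,pi->i", wvs * grho[:, ecomp], h, tmp)
                    t2 = np.einsum("p,pi,pi->i", wvs * grho[:, ecomp],
                                   aog[:, :, dcomp], Pg[:, :, ecomp])
                    tot += t1 + t2
                np.add.at(grad[:, dcomp], atom_of, -2.0 * tot)
    return grad
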