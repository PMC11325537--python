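"""Becke-partitioned molecular integration grid.

Radial: Mura-Knowles Log3 mapping.  Angular: product quadrature
(Gauss-Legendre in cos(theta) x uniform in phi), exact for spherical
harmonics up to the chosen degree.  Atomic weights: Becke's fuzzy-cell
partitioning with Bragg-Slater size adjustments.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

# Bragg-Slater radii in bohr (values in Angstrom / 0.52917721092)
_BOHR = 0.52917721092
BRAGG = {"H": 0.35 / _BOHR, "C": 0.70 / _BOHR, "N": 0.65 / _BOHR,
         "O": 0.60 / _BOHR}


def radial_mura_knowles(n: int, alpha: float = 5.0):
    """Mura-Knowles Log3 radial points and weights (includes r^2 factor)."""
    i = np.arange(1, n + 1)
    x = i / (n + 1.0)
    r = -alpha * np.log1p(-x ** 3)
    drdx = 3.0 * alpha * x ** 2 / (1.0 - x ** 3)
    w = drdx * r ** 2 / (n + 1.0)
    return r, w


def angular_product(n_theta: int):
    """Spherical product quadrature on the unit sphere; weights sum to 4*pi."""
    ct, wt = leggauss(n_theta)
    n_phi = 2 * n_theta
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - ct ** 2)
    pts = np.empty((n_theta * n_phi, 3))
    w = np.empty(n_theta * n_phi)
    k = 0
    for it in range(n_theta):
        for ip in range(n_phi):
            pts[k] = (st[it] * np.cos(phi[ip]), st[it] * np.sin(phi[ip]), ct[it])
            w[k] = wt[it] * 2.0 * np.pi / n_phi
            k += 1
    return pts, w


def _becke_weights(points, coords, radii, k=3):
    """Becke partition weight of each point w.r.t. every atom."""
    natom = len(coords)
    npts = len(points)
    # distances point-atom
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    # pairwise atom distances
    Rab = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    P = np.ones((npts, natom))
    for a in range(natom):
        for b in range(natom):
            if a == b:
                continue
            mu = (d[:, a] - d[:, b]) / Rab[a, b]
            # size adjustment (Becke appendix)
            chi = radii[a] / radii[b]
            u = (chi - 1.0) / (chi + 1.0)
            aab = np.clip(u / (u * u - 1.0), -0.5, 0.5)
            nu = mu + aab * (1.0 - mu ** 2)
            f = nu
            for _ in range(k):
                f = 1.5 * f - 0.5 * f ** 3
            P[:, a] *= 0.5 * (1.0 - f)
    tot = P.sum(axis=1)
    tot[tot == 0.0] = 1.0
    return P / tot[:, None]


class MolecularGrid:
    """Atom-centered quadrature grid for xc integration.

    Parameters are per-element (n_radial, n_theta); hydrogen gets a lighter
    grid by default, mirroring common practice.
    """

    def __init__(self, elements, coords, n_rad_heavy=75, n_theta_heavy=20,
                 n_rad_h=55, n_theta_h=16, prune_weight=1e-14):
        coords = np.asarray(coords, float)
        pts_all, w_all = [], []
        for ia, el in enumerate(elements):
            if el == "H":
                n_rad, n_theta = n_rad_h, n_theta_h
            else:
                n_rad, n_theta = n_rad_heavy, n_theta_heavy
            r, wr = radial_mura_knowles(n_rad)
            ang, wa = angular_product(n_theta)
            pts = (r[:, None, None] * ang[None, :, :]).reshape(-1, 3) + coords[ia]
            w = (wr[:, None] * wa[None, :]).reshape(-1)
            pts_all.append(pts)
            w_all.append(w)
        points = np.vstack(pts_all)
        w = np.concatenate(w_all)
        radii = np.array([BRAGG[e] for e in elements])
        # chunk the Becke weights to bound memory
        becke = np.empty(len(points))
        owner = np.concatenate([np.full(len(p), i) for i, p in enumerate(pts_all)])
        for lo in range(0, len(points), 200000):
            hi = min(lo + 200000, len(points))
            bw = _becke_weights(points[lo:hi], coords, radii)
            becke[lo:hi] = bw[np.arange(hi - lo), owner[lo:hi]]
        w = w * becke
        keep = w > prune_weight
        self.points = np.ascontiguousarray(points[keep])
        self.weights = np.ascontiguousarray(w[keep])

    def __len__(self):
        return len(self.points)
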