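"""Restricted Kohn-Sham / Hartree-Fock SCF for closed-shell molecules.

A conventional DIIS-accelerated Roothaan-Hall driver over the in-memory
integral tensors.  This is deliberately compact: density fitting, symmetry
and open shells are out of scope; it targets small molecules (~100 basis
functions) where the full ERI tensor fits in memory.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from . import integrals as ints
from .basis import build_basis
from .grid import MolecularGrid
from .xc import get_functional

HARTREE_EV = 27.211386245988


class SCFConvergenceError(RuntimeError):
    pass


class RestrictedSCFEngine:
    """Integral provider + SCF solver for one molecule.

    Parameters
    ----------
    elements, coords_bohr : molecular structure (coordinates in bohr)
    charge : total molecular charge
    functional : 'hf', 'lda' (SVWN5), 'blyp' or 'b3lyp'
    basis : basis-set name understood by build_basis
    grid_params : optional dict forwarded to MolecularGrid
    """

    def __init__(self, elements, coords_bohr, charge=0, functional="lda",
                 basis="6-31g**", grid_params=None):
        self.elements = list(elements)
        self.coords = np.asarray(coords_bohr, float)
        self.charge = charge
        self.functional = get_functional(functional)
        self.basis = build_basis(self.elements, self.coords, basis)
        self.n_electrons = int(sum(self.basis.charges) - charge)
        if self.n_electrons % 2:
            raise ValueError("restricted engine needs an even electron count")
        self.n_occ = self.n_electrons // 2
        self.grid_params = grid_params or {}
        self._cache = {}

    # --- integral accessors (cached) ---------------------------------------

    def overlap(self):
        return self._st()[0]

    def _st(self):
        if "st" not in self._cache:
            self._cache["st"] = ints.overlap_kinetic(self.basis)
        return self._cache["st"]

    def core_hamiltonian(self):
        if "h" not in self._cache:
            T = self._st()[1]
            V = ints.nuclear_attraction(self.basis)
            self._cache["h"] = T + V
        return self._cache["h"]

    def eri(self):
        if "eri" not in self._cache:
            self._cache["eri"] = ints.eri(self.basis)
        return self._cache["eri"]

    def nuclear_repulsion(self):
        return ints.nuclear_repulsion(self.basis.charges, self.coords)

    def _grid_ao(self):
        if "grid" not in self._cache:
            g = MolecularGrid(self.elements, self.coords, **self.grid_params)
            if self.functional.needs_sigma:
                ao, aograd = ints.ao_values(self.basis, g.points, deriv=1)
                self._cache["grid"] = (g, ao, aograd.astype(np.float32))
            else:
                ao = ints.ao_values(self.basis, g.points, deriv=0)
                self._cache["grid"] = (g, ao, None)
        return self._cache["grid"]

    def free_integrals(self):
        """Drop cached tensors (the ERI tensor dominates memory)."""
        self._cache.pop("eri", None)

    # --- xc quadrature ------------------------------------------------------

    def _exc_vxc(self, P):
        if not self.functional.pieces:
            return 0.0, 0.0
        g, ao, aograd = self._grid_ao()
        w = g.weights
        tmp = ao @ P
        rho = np.einsum("pi,pi->p", tmp, ao)
        np.clip(rho, 0.0, None, out=rho)
        if self.functional.needs_sigma:
            grho = 2.0 * np.einsum("pid,pi->pd",
                                   aograd.astype(np.float64), tmp)
            sigma = np.einsum("pd,pd->p", grho, grho)
            e, vrho, vsigma = self.functional.e_and_potential(rho, sigma)
        else:
            e, vrho, vsigma = self.functional.e_and_potential(rho)
        exc = float(w @ e)
        aoW = ao * (w * vrho)[:, None]
        V = ao.T @ aoW
        if self.functional.needs_sigma:
            # 2 vsigma grad(rho) . (grad(chi_mu) chi_nu + chi_mu grad(chi_nu))
            vec = 2.0 * (w * vsigma)[:, None] * grho
            M = np.einsum("pd,pid->pi", vec, aograd.astype(np.float64))
            V += M.T @ ao + ao.T @ M
        return exc, 0.5 * (V + V.T)

    # --- energy and Fock ----------------------------------------------------

    def energy_and_fock(self, P, external=None):
        """Total energy and Fock matrix at density P.

        external: optional extra one-electron operator (matrix, energy
        contribution handled by the caller via trace with P).
        """
        h = self.core_hamiltonian()
        eri4 = self.eri()
        J = np.einsum("pqrs,rs->pq", eri4, P)
        cx = self.functional.exact_exchange
        K = np.einsum("prqs,rs->pq", eri4, P) if cx else 0.0
        exc, vxc = self._exc_vxc(P)
        F = h + J - 0.5 * cx * K + vxc
        if external is not None:
            F = F + external
        E = (np.sum(P * h) + 0.5 * np.sum(P * J)
             - 0.25 * cx * np.sum(P * K) + exc
             + self.nuclear_repulsion())
        if external is not None:
            E += np.sum(P * external)
        return E, F

    # --- SCF ----------------------------------------------------------------

    def solve_ground_state(self, conv_tol=1e-8, max_iter=120, guess=None,
                           external=None, diis_size=8, verbose=False):
        """Converge the aufbau closed-shell SCF with DIIS.

        Returns an SCFSolution (imported lazily to keep layering simple).
        """
        from ..scf import SCFSolution

        S = self.overlap()
        X = _lowdin_x(S)
        if guess is None:
            h = self.core_hamiltonian()
            eps, C = sla.eigh(h, S)
        else:
            C = guess
        P = 2.0 * C[:, :self.n_occ] @ C[:, :self.n_occ].T
        errs, focks = [], []
        E_old, eps = 0.0, None
        for it in range(max_iter):
            E, F = self.energy_and_fock(P, external=external)
            err = X.T @ (F @ P @ S - S @ P @ F) @ X
            rms = np.sqrt(np.mean(err ** 2))
            if verbose:
                print(f"  scf iter {it:3d}  E={E:.10f}  dE={E - E_old:+.2e}  "
                      f"diis={rms:.2e}")
            if rms < conv_tol and it > 0:
                eps, C = sla.eigh(F, S)
                occ = np.zeros(len(eps))
                occ[:self.n_occ] = 2.0
                return SCFSolution(C=C, occ=occ, eps=eps, energy=E,
                                   converged=True, grad_rms=rms, n_iter=it,
                                   overlap=S)
            errs.append(err)
            focks.append(F)
            if len(errs) > diis_size:
                errs.pop(0)
                focks.pop(0)
            F_eff = _diis_extrapolate(focks, errs) if it >= 1 else F
            eps, C = sla.eigh(F_eff, S)
            P_new = 2.0 * C[:, :self.n_occ] @ C[:, :self.n_occ].T
            if it < 2 and guess is None:  # damp the first steps off core guess
                P = 0.3 * P + 0.7 * P_new
            else:
                P = P_new
            E_old = E
        raise SCFConvergenceError(
            f"SCF not converged in {max_iter} iterations (rms {rms:.2e})")


def _lowdin_x(S):
    s, U = np.linalg.eigh(S)
    keep = s > 1e-10
    return U[:, keep] / np.sqrt(s[keep])


def _diis_extrapolate(focks, errs):
    n = len(focks)
    B = np.empty((n + 1, n + 1))
    B[-1, :] = -1.0
    B[:, -1] = -1.0
    B[-1, -1] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.sum(errs[i] * errs[j])
    rhs = np.zeros(n + 1)
    rhs[-1] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return focks[-1]
    return sum(ci * Fi for ci, Fi in zip(c, focks))
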