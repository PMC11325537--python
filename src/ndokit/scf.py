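"""Solution-preparation protocols: guesses, occupation policies and a
quasi-Newton direct-minimization SCF solver.

The solver minimizes the total energy over orbital rotations C' = C exp(K)
with K antisymmetric and restricted to the occupied-virtual block, using
L-BFGS with three robustness rules: a bounded history, a history reset
whenever the RMS gradient crosses a threshold (in either direction), and a
history trim while the Gram matrix of the stored update vectors acquires a
(numerically) negative eigenvalue.  Steps are clipped so that no rotation
element exceeds the regularization threshold t_r.

Occupation policies:
  'fixed'  - occupations stay attached to the (continuously evolving) guess
             orbitals; this can converge to non-Aufbau stationary points
             where an occupied level lies above an empty one.
  'aufbau' - after each accepted step the occupied set is re-assigned to the
             lowest-energy orbitals (swapping clears the L-BFGS history).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg as sla

HARTREE_EV = 27.211386245988


class EngineCapabilityError(RuntimeError):
    """Raised when the requested computation exceeds the built-in engine.

    Matrix-archive workflows (NDO analysis, screening) do not need an
    engine; only solution preparation does.
    """


@dataclass
class SCFSolution:
    """A converged (or not) SCF solution.

    C: MO coefficients (AO basis, columns), occ: occupation numbers,
    eps: orbital energies in hartree, energy: total energy in hartree.
    """

    C: np.ndarray
    occ: np.ndarray
    eps: np.ndarray
    energy: float
    converged: bool
    grad_rms: float
    n_iter: int = 0
    overlap: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_electrons(self) -> float:
        return float(np.sum(self.occ))

    @property
    def homo_lumo_gap_ev(self) -> float:
        """Gap (eV) under the *stated* occupation pattern.

        For non-Aufbau occupations this is negative: the lowest empty level
        lies below the highest filled one.
        """
        filled = self.occ > 1e-8
        if filled.all() or not filled.any():
            raise ValueError("gap undefined: no partition into filled/empty")
        e_homo = self.eps[filled].max()
        e_lumo = self.eps[~filled].min()
        return (e_lumo - e_homo) * HARTREE_EV

    @property
    def density(self) -> np.ndarray:
        return (self.C * self.occ) @ self.C.T

    def validate(self, S=None, tol=1e-8):
        S = self.overlap if S is None else S
        if S is not None:
            dev = np.abs(self.C.T @ S @ self.C - np.eye(self.C.shape[1])).max()
            if dev > tol:
                raise ValueError(f"orbitals not S-orthonormal (dev {dev:.2e})")
        return self


@dataclass
class GuessSpec:
    """How to prepare initial orbitals: 'fragment_disjoint' or 'perturbed'."""

    mode: str = "perturbed"
    seed: int = 0
    magnitude: float = 0.01

    def __post_init__(self):
        if self.mode not in ("fragment_disjoint", "perturbed"):
            raise ValueError(f"unknown guess mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class QNConfig:
    """Quasi-Newton solver settings.

    m: L-BFGS history size; t_r: step regularization (largest allowed
    rotation element); grad_reset: RMS-gradient level whose crossing (in
    either direction) clears the history; trim_floor: the history is trimmed
    oldest-first while the smallest eigenvalue of V^T V (V = stored s and y
    vectors) lies below this floor.
    """

    m: int = 15
    t_r: float = 0.15
    grad_reset: float = 1e-6
    trim_floor: float = -1e-15
    max_iter: int = 500
    conv_tol: float = 1e-7

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("history size m must be >= 1")
        for name in ("t_r", "grad_reset", "conv_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# guesses
# ---------------------------------------------------------------------------

def perturb_orbitals(C, S, spec: GuessSpec):
    """Apply a small random orthogonal rotation mixing all orbitals.

    C' = C exp(K), K antisymmetric with entries uniform in
    [-magnitude, +magnitude]; the same seed and magnitude reproduce the
    same rotation exactly.
    """
    C = np.asarray(C, float)
    n = C.shape[1]
    dev = np.abs(C.T @ S @ C - np.eye(n)).max()
    if dev > 1e-8:
        raise ValueError(f"guess orbitals not S-orthonormal (dev {dev:.2e})")
    if spec.magnitude == 0.0:
        return C.copy()
    rng = np.random.default_rng(spec.seed)
    A = rng.uniform(-spec.magnitude, spec.magnitude, size=(n, n))
    K = np.tril(A, -1)
    K = K - K.T
    return C @ sla.expm(K)


def build_disjoint_guess(fragment_solutions, S, separation_tol=1e-10):
    """Block-embed separately converged fragment orbitals into a supersystem.

    The fragments' AO blocks must not overlap: the inter-fragment blocks of
    S are checked against separation_tol.  Occupations are inherited from
    each fragment's own ground state, so the global pattern may be
    non-Aufbau.

    Returns (C, occ, eps) for the supersystem.
    """
    sizes = [sol.C.shape[0] for sol in fragment_solutions]
    n = sum(sizes)
    if S.shape != (n, n):
        raise ValueError("supersystem overlap dimension mismatch")
    off = np.cumsum([0] + sizes)
    for i in range(len(sizes)):
        for j in range(i):
            blk = S[off[i]:off[i + 1], off[j]:off[j + 1]]
            mx = np.abs(blk).max()
            if mx > separation_tol:
                raise ValueError(
                    f"fragments {j} and {i} are not separated: "
                    f"max inter-fragment overlap {mx:.2e} > {separation_tol:g}")
    nmo = sum(sol.C.shape[1] for sol in fragment_solutions)
    C = np.zeros((n, nmo))
    occ = np.concatenate([sol.occ for sol in fragment_solutions])
    eps = np.concatenate([sol.eps for sol in fragment_solutions])
    col = 0
    for i, sol in enumerate(fragment_solutions):
        k = sol.C.shape[1]
        C[off[i]:off[i + 1], col:col + k] = sol.C
        col += k
    return C, occ, eps


# ---------------------------------------------------------------------------
# L-BFGS machinery
# ---------------------------------------------------------------------------

class _LBFGSHistory:
    def __init__(self, m, trim_floor):
        self.m = m
        self.trim_floor = trim_floor
        self.s: list[np.ndarray] = []
        self.y: list[np.ndarray] = []

    def clear(self):
        self.s.clear()
        self.y.clear()

    def push(self, s, y):
        if float(s @ y) <= 1e-14:  # keep the inverse Hessian positive
            return
        self.s.append(s)
        self.y.append(y)
        if len(self.s) > self.m:
            self.s.pop(0)
            self.y.pop(0)
        self._trim()

    def _trim(self):
        while self.s:
            V = np.column_stack(self.s + self.y)
            lam = np.linalg.eigvalsh(V.T @ V)[0]
            if lam < self.trim_floor:
                self.s.pop(0)
                self.y.pop(0)
            else:
                break

    def direction(self, g, h0=None):
        """Two-loop recursion for -H g.

        h0: optional per-coordinate initial Hessian diagonal (e.g. the
        occupied-virtual orbital-energy differences); without it the
        standard Barzilai-Borwein scaling is used.
        """
        q = g.copy()
        alphas = []
        for s, y in zip(reversed(self.s), reversed(self.y)):
            rho = 1.0 / (y @ s)
            a = rho * (s @ q)
            alphas.append(a)
            q -= a * y
        if h0 is not None:
            q = q / h0
        elif self.s:
            gamma = (self.s[-1] @ self.y[-1]) / (self.y[-1] @ self.y[-1])
            q *= gamma
        for (s, y), a in zip(zip(self.s, self.y), reversed(alphas)):
            rho = 1.0 / (y @ s)
            b = rho * (y @ q)
            q += (a - b) * s
        return -q


# ---------------------------------------------------------------------------
# the minimizer
# ---------------------------------------------------------------------------

def qn_minimize(engine, C0, occ, policy="aufbau", config: QNConfig | None = None,
                verbose=False, callback=None):
    """Minimize the total energy over occupied-virtual orbital rotations.

    engine must expose overlap() and energy_and_fock(P) -> (E, F).
    C0: S-orthonormal starting orbitals (n x nmo); occ: occupation numbers
    aligned with C0's columns.  Returns an SCFSolution; if max_iter is
    exhausted the solution is returned with converged=False (no exception).
    """
    if config is None:
        config = QNConfig()
    if policy not in ("aufbau", "fixed"):
        raise ValueError(f"unknown occupation policy {policy!r}")
    S = engine.overlap()
    C = np.asarray(C0, float).copy()
    occ = np.asarray(occ, float).copy()
    nmo = C.shape[1]
    # order columns occupied-first to keep the K block contiguous
    order = np.argsort(-occ, kind="stable")
    C, occ = C[:, order], occ[order]
    iocc = np.where(occ > 1e-8)[0]
    ivir = np.where(occ <= 1e-8)[0]
    no, nv = len(iocc), len(ivir)
    hist = _LBFGSHistory(config.m, config.trim_floor)
    prev_rms = None
    E = None
    n_eval = 0
    trace = []

    def eval_at(Cmat):
        nonlocal n_eval
        P = (Cmat * occ) @ Cmat.T
        n_eval += 1
        return engine.energy_and_fock(P)

    E, F = eval_at(C)
    for it in range(config.max_iter):
        if policy == "aufbau":
            C_new, occ_new, swapped = _aufbau_reassign(C, occ, F)
            if swapped:
                P_new = (C_new * occ_new) @ C_new.T
                E_new, F_new = engine.energy_and_fock(P_new)
                n_eval += 1
                if E_new <= E + 1e-12:  # refill only when it descends
                    C, occ, E, F = C_new, occ_new, E_new, F_new
                    hist.clear()
                    prev_rms = None
                    iocc = np.where(occ > 1e-8)[0]
                    ivir = np.where(occ <= 1e-8)[0]
        Fmo = C.T @ F @ C
        # gradient wrt K_ia (i occupied, a virtual)
        docc = occ[ivir][None, :] - occ[iocc][:, None]
        G = 2.0 * docc * Fmo[np.ix_(iocc, ivir)]
        g = G.ravel()
        rms = np.sqrt(np.mean(g * g)) if g.size else 0.0
        trace.append((E, rms))
        if callback is not None:
            callback(it, E, rms)
        if verbose:
            print(f"  qn iter {it:4d}  E={E:.10f}  grad_rms={rms:.3e}")
        if rms < config.conv_tol:
            return _finalize(engine, C, occ, F, S, E, True, rms, it, trace)
        # history reset on threshold crossing, either direction
        if prev_rms is not None and (
                (prev_rms > config.grad_reset) != (rms > config.grad_reset)):
            hist.clear()
        prev_rms = rms
        # diagonal preconditioner: |d2E/dK_ia^2| ~ 2|occ_i - occ_a| *
        # (F_aa - F_ii), floored to keep soft/non-Aufbau modes bounded
        diag = np.diag(Fmo)
        h0 = 2.0 * np.abs(docc) * np.abs(diag[ivir][None, :]
                                         - diag[iocc][:, None])
        h0 = np.maximum(h0.ravel(), 0.2)
        d = hist.direction(g, h0=h0)
        if d @ g >= 0.0:  # not a descent direction; steepest descent restart
            hist.clear()
            d = -g
        # clip so the largest rotation element stays within t_r
        mx = np.abs(d).max() if d.size else 0.0
        if mx > config.t_r:
            d *= config.t_r / mx
        # backtracking line search on the energy
        step = 1.0
        accepted = False
        gd = g @ d
        for _ in range(12):
            K = np.zeros((nmo, nmo))
            K[np.ix_(iocc, ivir)] = (step * d).reshape(no, nv)
            K -= K.T
            C_try = C @ sla.expm(K)
            E_try, F_try = eval_at(C_try)
            if E_try <= E + 1e-4 * step * gd or abs(E_try - E) < 1e-14:
                accepted = True
                break
            step *= 0.4
        if not accepted:
            hist.clear()
            continue
        # gradient at the new point for the curvature pair
        Fmo_new = C_try.T @ F_try @ C_try
        G_new = 2.0 * docc * Fmo_new[np.ix_(iocc, ivir)]  # docc already ivir-iocc
        g_new = G_new.ravel()
        hist.push(step * d, g_new - g)
        C, E, F = C_try, E_try, F_try
    Fmo = C.T @ F @ C
    docc = occ[ivir][None, :] - occ[iocc][:, None]
    g = (2.0 * docc * Fmo[np.ix_(iocc, ivir)]).ravel()
    rms = np.sqrt(np.mean(g * g)) if g.size else 0.0
    return _finalize(engine, C, occ, F, S, E, False, rms, config.max_iter, trace)


def _aufbau_reassign(C, occ, F):
    """Re-sort orbitals by energy and refill from the bottom."""
    eps = np.einsum("mi,mn,ni->i", C, F, C)
    order = np.argsort(eps, kind="stable")
    occ_sorted = -np.sort(-occ, kind="stable")  # descending occupations
    C_new = C[:, order]
    swapped = bool(np.any(np.abs(occ[order] - occ_sorted) > 1e-12))
    return C_new, occ_sorted, swapped


def _finalize(engine, C, occ, F, S, E, converged, rms, n_iter, trace):
    # canonicalize within the occupied and virtual subspaces (invariant to E)
    iocc = np.where(occ > 1e-8)[0]
    ivir = np.where(occ <= 1e-8)[0]
    Fmo = C.T @ F @ C
    C = C.copy()
    eps = np.empty(C.shape[1])
    for idx in (iocc, ivir):
        if len(idx) == 0:
            continue
        w, U = np.linalg.eigh(Fmo[np.ix_(idx, idx)])
        C[:, idx] = C[:, idx] @ U
        eps[idx] = w
    return SCFSolution(C=C, occ=occ, eps=eps, energy=E, converged=converged,
                       grad_rms=rms, n_iter=n_iter, overlap=S,
                       meta={"trace": trace})


# ---------------------------------------------------------------------------
# engine adapter
# ---------------------------------------------------------------------------

def engine_adapter(geometry, basis="6-31g**", functional="lda", charge=0,
                   settings=None):
    """Build an SCF engine for a molecular geometry.

    geometry: (elements, coords_bohr) tuple, or a path to an XYZ/PDB file.
    Returns the engine object, which exposes overlap(),
    energy_and_fock(P) and solve_ground_state().

    Raises EngineCapabilityError for inputs the built-in engine cannot
    treat (unsupported elements, odd electron counts); matrix-archive
    workflows remain fully available in that case.
    """
    settings = settings or {}
    if isinstance(geometry, (str, bytes)) or hasattr(geometry, "__fspath__"):
        from .io import read_geometry
        elements, coords = read_geometry(geometry)
    else:
        elements, coords = geometry
    from .engine.rks import RestrictedSCFEngine
    try:
        return RestrictedSCFEngine(elements, coords, charge=charge,
                                   functional=functional, basis=basis,
                                   **settings)
    except ValueError as exc:
        raise EngineCapabilityError(
            f"built-in engine cannot treat this system ({exc}); "
            "use matrix-archive workflows for analysis-only tasks") from exc
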