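"""Natural deformation orbitals (NDOs).

Two converged one-particle density matrices describing the same molecule
with different methods are compared by diagonalizing their difference in
an orthonormalized basis:

    Delta = X^T S (P_ref - P_cmp) S X,      Delta u_k = q_k u_k,

with X a Loewdin (symmetric) orthonormalizer, X^T S X = 1.  The
eigenvectors back-transformed to the AO basis, v_k = X u_k, are the
natural deformation orbitals; the eigenvalues q_k ("deformation
charges") tell how much electron density each orbital carries between
the two solutions.  With the convention ref = higher-level method (e.g.
Hartree-Fock) and cmp = the KS solution under scrutiny, a *negative*
q_k marks density the comparison method has gained.

The spectrum is invariant to the orthonormalization choice (absent
linear-dependence dropping); Loewdin is used because it stays closest to
the original AOs and hence keeps the NDOs atom-attributable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

HARTREE_EV = 27.211386245988


class InvalidOverlapError(ValueError):
    pass


class DimensionMismatchError(ValueError):
    pass


@dataclass
class DensityMatrix:
    """Spin-summed one-particle density matrix in the AO basis.

    For a closed-shell single-determinant source, P S P = 2 P and
    Tr(P S) equals the electron count.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise DimensionMismatchError("density matrix must be square")
        asym = np.abs(self.values - self.values.T).max()
        if asym > 1e-10:
            raise ValueError(f"density matrix not symmetric (dev {asym:.2e})")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def electron_count(self, S) -> float:
        return float(np.trace(self.values @ S))

    def idempotency_defect(self, S) -> float:
        """max |P S P - 2 P|; ~0 for closed-shell single determinants."""
        P = self.values
        return float(np.abs(P @ S @ P - 2.0 * P).max())

    def validate(self, S, idem_tol=1e-6, count_tol=1e-6):
        defect = self.idempotency_defect(S)
        if defect > idem_tol:
            raise ValueError(
                f"density not idempotent (|PSP-2P| = {defect:.2e})")
        ne = self.electron_count(S)
        if abs(ne - round(ne)) > count_tol:
            raise ValueError(f"non-integer electron count {ne!r}")
        return self


@dataclass
class Orthonormalizer:
    """Transformation X with X^T S X = 1 (columns may be fewer than rows
    when near-null overlap directions are dropped)."""

    X: np.ndarray
    lindep_tol: float
    n_dropped: int
    kind: str = "lowdin"

    def check(self, S, tol=1e-10):
        dev = np.abs(self.X.T @ S @ self.X
                     - np.eye(self.X.shape[1])).max()
        if dev > tol:
            raise ValueError(f"X^T S X deviates from identity by {dev:.2e}")
        return self


def lowdin_orthonormalizer(S, lindep_tol=1e-8) -> Orthonormalizer:
    """Symmetric (Loewdin) inverse square root of the overlap.

    Overlap eigenvalues below lindep_tol are dropped (counted in
    n_dropped); an indefinite overlap raises InvalidOverlapError.
    """
    S = np.asarray(S, float)
    s, U = np.linalg.eigh((S + S.T) / 2.0)
    if s[0] < -1e-10:
        raise InvalidOverlapError(
            f"overlap has negative eigenvalue {s[0]:.3e}")
    keep = s > lindep_tol
    n_dropped = int((~keep).sum())
    Uk = U[:, keep]
    if n_dropped == 0:
        # true symmetric S^(-1/2)
        X = (Uk / np.sqrt(s[keep])) @ Uk.T
    else:
        X = Uk / np.sqrt(s[keep])
    return Orthonormalizer(X=X, lindep_tol=lindep_tol, n_dropped=n_dropped)


def canonical_orthonormalizer(S, lindep_tol=1e-8) -> Orthonormalizer:
    """Canonical orthogonalization U s^(-1/2); used to test the
    orthonormalization-invariance of the NDO spectrum."""
    S = np.asarray(S, float)
    s, U = np.linalg.eigh((S + S.T) / 2.0)
    if s[0] < -1e-10:
        raise InvalidOverlapError(
            f"overlap has negative eigenvalue {s[0]:.3e}")
    keep = s > lindep_tol
    X = U[:, keep] / np.sqrt(s[keep])
    return Orthonormalizer(X=X, lindep_tol=lindep_tol,
                           n_dropped=int((~keep).sum()), kind="canonical")


@dataclass
class NDOSet:
    """Deformation charges (sorted descending) and AO-basis NDO vectors."""

    q_nd: np.ndarray
    vectors: np.ndarray  # (n_ao, n_ndo), S-orthonormal columns
    labels: tuple = ("ref", "cmp")

    def __len__(self):
        return len(self.q_nd)

    def frontier(self, threshold: float = 0.2) -> "NDOSet":
        """Subset with |q_nd| >= threshold (frontier NDOs), order kept."""
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        keep = np.abs(self.q_nd) >= threshold
        return NDOSet(q_nd=self.q_nd[keep], vectors=self.vectors[:, keep],
                      labels=self.labels)

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.q_nd).max()) if len(self) else 0.0

    def validate(self, S, electron_diff=0.0, tol=1e-8):
        if np.any(np.diff(self.q_nd) > tol):
            raise ValueError("q_nd not sorted descending")
        if np.abs(self.q_nd).max(initial=0.0) > 2.0 + 1e-8:
            raise ValueError("|q_nd| exceeds the closed-shell bound 2")
        dev = np.abs(self.vectors.T @ S @ self.vectors
                     - np.eye(self.vectors.shape[1])).max()
        if dev > tol:
            raise ValueError(f"NDOs not S-orthonormal (dev {dev:.2e})")
        if abs(self.q_nd.sum() - electron_diff) > max(tol, 1e-8):
            raise ValueError("sum of q_nd does not match electron difference")
        return self

    def to_report(self) -> dict:
        return {
            "labels": list(self.labels),
            "sign_convention": "negative q_nd marks density gained by "
                               f"{self.labels[1]} relative to {self.labels[0]}",
            "q_nd": self.q_nd.tolist(),
        }


def compute_ndos(P_ref, P_cmp, S, ortho: Optional[Orthonormalizer] = None,
                 labels=("ref", "cmp"), partition=None,
                 atom_of_basis=None) -> NDOSet:
    """Diagonalize the density difference P_ref - P_cmp in an orthonormal
    basis and return the NDOs in the AO basis.

    P_ref / P_cmp may be DensityMatrix objects or plain arrays.  A
    mismatch in electron counts larger than 1e-4 triggers a warning (not
    an error: comparisons between ionized or fractional-charge solutions
    are legitimate).  Near-degenerate eigenvalues are ordered by leading
    fragment population when a partition (+ atom_of_basis) is supplied,
    then by original index, making the output deterministic.
    """
    A = P_ref.values if isinstance(P_ref, DensityMatrix) else np.asarray(P_ref, float)
    B = P_cmp.values if isinstance(P_cmp, DensityMatrix) else np.asarray(P_cmp, float)
    S = np.asarray(S, float)
    if A.shape != B.shape or A.shape != S.shape:
        raise DimensionMismatchError(
            f"dimension mismatch: P_ref {A.shape}, P_cmp {B.shape}, S {S.shape}")
    n_ref = float(np.trace(A @ S))
    n_cmp = float(np.trace(B @ S))
    if abs(n_ref - n_cmp) > 1e-4:
        warnings.warn(
            f"electron counts differ: Tr(P_ref S) = {n_ref:.6f}, "
            f"Tr(P_cmp S) = {n_cmp:.6f}; sum of q_nd will equal the difference",
            stacklevel=2)
    if ortho is None:
        ortho = lowdin_orthonormalizer(S)
    X = ortho.X
    D = X.T @ (S @ (A - B) @ S) @ X
    q, U = np.linalg.eigh((D + D.T) / 2.0)
    V = X @ U
    # descending by q, stable in the original (ascending-eigh) order
    order = np.argsort(-q, kind="stable")
    q, V = q[order], V[:, order]
    if partition is not None and atom_of_basis is not None:
        q, V = _tie_break(q, V, S, partition, atom_of_basis)
    return NDOSet(q_nd=q, vectors=V, labels=tuple(labels))


def _tie_break(q, V, S, partition, atom_of_basis, tol=1e-10):
    """Order degenerate eigenvalues by larger leading-fragment population."""
    from .fragments import mulliken_orbital_populations

    i = 0
    q = q.copy()
    V = V.copy()
    n = len(q)
    while i < n:
        j = i + 1
        while j < n and abs(q[j] - q[i]) < tol:
            j += 1
        if j - i > 1:
            keys = []
            for k in range(i, j):
                pops = mulliken_orbital_populations(
                    V[:, k], S, partition, atom_of_basis)
                keys.append((-float(np.max(pops)), k))
            order = [k for _, k in sorted(keys)]
            q[i:j] = q[order]
            V[:, i:j] = V[:, order]
        i = j
    return q, V
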