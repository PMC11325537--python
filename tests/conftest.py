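import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def random_spd(n, seed, scale=1.0):
    """Well-conditioned random SPD matrix with unit-ish diagonal."""
    r = np.random.default_rng(seed)
    A = r.normal(size=(n, n))
    S = A.T @ A + n * np.eye(n)
    d = np.sqrt(np.diag(S))
    return scale * S / np.outer(d, d)


def random_idempotent_density(S, n_occ, seed, occ=2.0):
    """Random closed-shell-style density: P = occ * C C^T, C^T S C = 1."""
    r = np.random.default_rng(seed)
    n = S.shape[0]
    C = r.normal(size=(n, n_occ))
    # S-orthonormalize
    M = C.T @ S @ C
    w, U = np.linalg.eigh(M)
    C = C @ U / np.sqrt(w)
    return occ * C @ C.T


@pytest.fixture(scope="session")
def h2_engines():
    """Small converged engine solutions reused across IO/engine tests."""
    from ndokit.engine.rks import RestrictedSCFEngine

    hf = RestrictedSCFEngine(["H", "H"], [[0, 0, 0], [0, 0, 1.4]],
                             functional="hf", basis="sto-3g")
    sol_hf = hf.solve_ground_state(conv_tol=1e-10)
    lda = RestrictedSCFEngine(["H", "H"], [[0, 0, 0], [0, 0, 1.4]],
                              functional="lda", basis="6-31g**")
    sol_lda = lda.solve_ground_state(conv_tol=1e-10)
    return {"hf": (hf, sol_hf), "lda": (lda, sol_lda)}
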