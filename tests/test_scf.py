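"""Guess machinery and the quasi-Newton orbital-rotation minimizer."""

import numpy as np
import pytest
import scipy.linalg as sla

from ndokit.scf import (GuessSpec, QNConfig, SCFSolution,
                        build_disjoint_guess, perturb_orbitals, qn_minimize)
from ndokit.synthetic import make_toy_ct_model

from conftest import random_spd


class LinearBlockEngine:
    """E(P) = Tr(h P) with block-diagonal h and S = 1.

    The eigenvectors of h are exact stationary points, so a disjoint
    guess built from per-block eigen-solutions has *identically* zero
    rotation gradient: the minimal model of non-interacting fragments.
    """

    def __init__(self, blocks):
        self.h = sla.block_diag(*blocks)

    def overlap(self):
        return np.eye(self.h.shape[0])

    def energy_and_fock(self, P):
        return float(np.sum(self.h * P)), self.h


def eigensolution(h, occ):
    eps, C = np.linalg.eigh(h)
    return SCFSolution(C=C, occ=np.asarray(occ, float), eps=eps,
                       energy=float((np.asarray(occ) * eps).sum()),
                       converged=True, grad_rms=0.0,
                       overlap=np.eye(len(eps)))


class TestPerturbOrbitals:
    def test_zero_magnitude_is_identity(self):
        S = random_spd(8, seed=1)
        C = _orthonormal(S, seed=2)
        spec = GuessSpec(mode="perturbed", seed=5, magnitude=0.0)
        np.testing.assert_array_equal(perturb_orbitals(C, S, spec), C)

    def test_orthonormality_preserved(self):
        S = np.eye(12)
        C = _orthonormal(S, seed=3)
        C2 = perturb_orbitals(C, S, GuessSpec(seed=9, magnitude=0.01))
        assert np.abs(C2.T @ S @ C2 - np.eye(12)).max() < 1e-10
        # also with a nontrivial metric
        S = random_spd(12, seed=4)
        C = _orthonormal(S, seed=5)
        C2 = perturb_orbitals(C, S, GuessSpec(seed=9, magnitude=0.01))
        assert np.abs(C2.T @ S @ C2 - np.eye(12)).max() < 1e-10

    def test_seeded_and_distinct(self):
        S = np.eye(10)
        C = _orthonormal(S, seed=6)
        a = perturb_orbitals(C, S, GuessSpec(seed=1, magnitude=0.01))
        b = perturb_orbitals(C, S, GuessSpec(seed=1, magnitude=0.01))
        c = perturb_orbitals(C, S, GuessSpec(seed=2, magnitude=0.01))
        np.testing.assert_array_equal(a, b)
        assert np.abs(a - c).max() > 0.0

    def test_non_orthonormal_guess_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            perturb_orbitals(np.ones((4, 4)), np.eye(4), GuessSpec(seed=0))


def _orthonormal(S, seed):
    r = np.random.default_rng(seed)
    C = r.normal(size=S.shape)
    for _ in range(2):  # repeat the whitening to refine conditioning
        M = C.T @ S @ C
        w, U = np.linalg.eigh(M)
        C = C @ U / np.sqrt(w)
    return C


class TestDisjointGuess:
    def test_block_embedding_is_orthonormal(self):
        h1 = np.diag([-2.0, 1.0]) + 0.1
        h2 = np.diag([-1.0, 2.0]) - 0.05
        s1 = eigensolution(h1, [2, 0])
        s2 = eigensolution(h2, [2, 0])
        S = np.eye(4)
        C, occ, eps = build_disjoint_guess([s1, s2], S)
        assert np.abs(C.T @ S @ C - np.eye(4)).max() < 1e-12
        assert C[2:, :2].max() == 0.0 and C[:2, 2:].max() == 0.0

    def test_separated_fragments_required(self):
        s1 = eigensolution(np.diag([-1.0, 1.0]), [2, 0])
        s2 = eigensolution(np.diag([-1.0, 1.0]), [2, 0])
        S = np.eye(4)
        S[0, 2] = S[2, 0] = 1e-6
        with pytest.raises(ValueError, match="not separated"):
            build_disjoint_guess([s1, s2], S)

    def test_global_gap_is_minimum_over_pair_gaps(self):
        """Two planted two-level fragments: the supersystem gap under the
        inherited occupations equals the brute-force minimum of
        eps_LUMO(a) - eps_HOMO(d) over the 2x2 fragment-level set."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            e1 = np.sort(rng.uniform(-1, 1, size=2))
            e2 = np.sort(rng.uniform(-1, 1, size=2))
            s1 = eigensolution(np.diag(e1), [2, 0])
            s2 = eigensolution(np.diag(e2), [2, 0])
            C, occ, eps = build_disjoint_guess([s1, s2], np.eye(4))
            filled = occ > 0
            gap = eps[~filled].min() - eps[filled].max()
            homos = [e1[0], e2[0]]
            lumos = [e1[1], e2[1]]
            brute = min(lumos[a] - homos[d]
                        for d in range(2) for a in range(2))
            assert gap == pytest.approx(brute, abs=1e-12)


class TestQNMinimize:
    def test_concave_toy_model_recovery(self):
        """Fractional-transfer minimum x* = 1/2 - delta/(2 gamma)."""
        m = make_toy_ct_model(1.0, -4.0)
        C0, occ = m.guess(0.02)
        sol = qn_minimize(m, C0, occ, policy="fixed",
                          config=QNConfig(conv_tol=1e-10))
        assert sol.converged
        x = sol.density[1, 1]
        assert x == pytest.approx(0.625, abs=1e-6)
        assert sol.energy == pytest.approx(m.energy(m.x_star), abs=1e-10)
        # grid-search oracle agrees
        xg, eg = m.grid_minimum()
        assert x == pytest.approx(xg, abs=1e-6)

    def test_positive_curvature_descends_to_integer_transfer(self):
        # starting beyond the barrier, descent reaches x = 1
        m = make_toy_ct_model(1.0, 2.0)
        C0, occ = m.guess(0.6)
        sol = qn_minimize(m, C0, occ, policy="fixed",
                          config=QNConfig(conv_tol=1e-9))
        assert sol.density[1, 1] == pytest.approx(1.0, abs=1e-6)

    def test_unperturbed_disjoint_guess_has_zero_gradient(self):
        """Block-separated fragments: inter-fragment rotation gradients are
        identically zero, so the non-Aufbau occupation pattern survives
        minimization unchanged."""
        # fragment 1: HOMO above fragment 2's LUMO (non-Aufbau globally)
        h1 = np.diag([0.5, 5.0]) / 27.211
        h2 = np.diag([-12.0, -6.5]) / 27.211
        eng = LinearBlockEngine([h1, h2])
        s1 = eigensolution(h1, [2, 0])
        s2 = eigensolution(h2, [2, 0])
        C, occ, eps = build_disjoint_guess([s1, s2], eng.overlap())
        sol = qn_minimize(eng, C, occ, policy="fixed",
                          config=QNConfig(conv_tol=1e-12))
        assert sol.converged and sol.n_iter == 0
        assert sol.grad_rms == 0.0
        # occupations still sit on the fragment levels: negative gap kept
        assert sol.homo_lumo_gap_ev < 0.0
        filled = sol.occ > 0
        assert sol.eps[filled].max() > sol.eps[~filled].min()

    def test_aufbau_policy_fills_lowest_levels(self):
        h1 = np.diag([0.5, 5.0]) / 27.211
        h2 = np.diag([-12.0, -6.5]) / 27.211
        eng = LinearBlockEngine([h1, h2])
        s1 = eigensolution(h1, [2, 0])
        s2 = eigensolution(h2, [2, 0])
        C, occ, _ = build_disjoint_guess([s1, s2], eng.overlap())
        sol = qn_minimize(eng, C, occ, policy="aufbau",
                          config=QNConfig(conv_tol=1e-12))
        # for a linear model the occupied set snaps to the two lowest levels
        assert sol.homo_lumo_gap_ev > 0.0
        assert sol.energy < (occ * np.concatenate([np.diag(h1),
                                                   np.diag(h2)])).sum() + 1e-12

    def test_max_iter_returns_unconverged_solution(self):
        m = make_toy_ct_model(1.0, -4.0)
        C0, occ = m.guess(0.02)
        sol = qn_minimize(m, C0, occ, policy="fixed",
                          config=QNConfig(max_iter=2, conv_tol=1e-14))
        assert not sol.converged
        assert np.isfinite(sol.energy)

    def test_energy_non_increasing_along_accepted_steps(self):
        m = make_toy_ct_model(0.7, -3.0)
        C0, occ = m.guess(0.05)
        sol = qn_minimize(m, C0, occ, policy="fixed",
                          config=QNConfig(conv_tol=1e-11))
        energies = [e for e, _ in sol.meta["trace"]]
        diffs = np.diff(energies)
        assert (diffs <= 1e-12).all()

    def test_invalid_policy_and_config_rejected(self):
        m = make_toy_ct_model(1.0, -4.0)
        C0, occ = m.guess(0.1)
        with pytest.raises(ValueError, match="policy"):
            qn_minimize(m, C0, occ, policy="maximum-overlap")
        with pytest.raises(ValueError):
            QNConfig(m=0)
        with pytest.raises(ValueError):
            QNConfig(t_r=-0.1)

    def test_step_clipping_respects_tr(self):
        """With a tiny t_r the solver still converges (more iterations)."""
        m = make_toy_ct_model(1.0, -4.0)
        C0, occ = m.guess(0.02)
        sol_small = qn_minimize(m, C0, occ, policy="fixed",
                                config=QNConfig(t_r=0.01, conv_tol=1e-9,
                                                max_iter=2000))
        assert sol_small.converged
        assert sol_small.density[1, 1] == pytest.approx(0.625, abs=1e-5)

    def test_history_reset_threshold_does_not_break_convergence(self):
        m = make_toy_ct_model(1.0, -4.0)
        C0, occ = m.guess(0.02)
        sol = qn_minimize(m, C0, occ, policy="fixed",
                          config=QNConfig(grad_reset=1e-2, conv_tol=1e-9))
        assert sol.converged
        assert sol.density[1, 1] == pytest.approx(0.625, abs=1e-5)
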