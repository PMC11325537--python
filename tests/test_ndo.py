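"""Eigenanalysis of density-matrix differences."""

import numpy as np
import pytest
import scipy.linalg as sla

from ndokit.ndo import (DensityMatrix, DimensionMismatchError,
                        InvalidOverlapError, canonical_orthonormalizer,
                        compute_ndos, lowdin_orthonormalizer)
from ndokit.synthetic import SyntheticCTSpec, make_ct_pair

from conftest import random_spd, random_idempotent_density


class TestLowdinOrthonormalizer:
    def test_identity_overlap_gives_identity(self):
        o = lowdin_orthonormalizer(np.eye(7))
        assert o.n_dropped == 0
        np.testing.assert_allclose(o.X, np.eye(7), atol=1e-12)

    def test_random_spd_overlap_orthonormalizes(self):
        S = random_spd(20, seed=7)
        o = lowdin_orthonormalizer(S)
        dev = np.abs(o.X.T @ S @ o.X - np.eye(20)).max()
        assert dev < 1e-10

    def test_near_null_direction_dropped(self):
        # S with one eigenvalue 1e-12: cut at lindep_tol 1e-8
        r = np.random.default_rng(0)
        Q, _ = np.linalg.qr(r.normal(size=(6, 6)))
        s = np.array([1e-12, 0.5, 0.8, 1.0, 1.3, 2.0])
        S = (Q * s) @ Q.T
        o = lowdin_orthonormalizer(S, lindep_tol=1e-8)
        assert o.n_dropped == 1
        assert o.X.shape == (6, 5)
        o.check(S)

    def test_indefinite_overlap_rejected(self):
        S = np.diag([1.0, 1.0, -0.2])
        with pytest.raises(InvalidOverlapError):
            lowdin_orthonormalizer(S)


class TestComputeNDOs:
    def test_equal_densities_give_zero_spectrum(self):
        S = random_spd(8, seed=3)
        P = random_idempotent_density(S, 3, seed=4)
        nd = compute_ndos(P, P, S)
        np.testing.assert_allclose(nd.q_nd, 0.0, atol=1e-12)

    @pytest.mark.parametrize("theta_deg", [5.0, 15.0, 30.0, 45.0, 60.0, 85.0])
    @pytest.mark.parametrize("channels,overlap", [
        (1, "identity"), (2, "random_spd_block")])
    def test_single_transfer_recovers_rotation_angle(self, theta_deg,
                                                     channels, overlap):
        """Leading q_nd = +/- occ*sin(theta), exactly, for planted rotations."""
        theta = np.deg2rad(theta_deg)
        res = make_ct_pair(SyntheticCTSpec(
            theta=theta, spin_channels=channels, seed=11,
            overlap_mode=overlap))
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        expect = channels * np.sin(theta)
        assert abs(nd.q_nd[0] - expect) < 1e-8
        assert abs(nd.q_nd[-1] + expect) < 1e-8
        recovered = np.arcsin(nd.q_nd[0] / channels)
        assert abs(recovered - theta) < 1e-8
        nd.validate(a.S)

    def test_theta30_single_channel_is_half(self):
        res = make_ct_pair(SyntheticCTSpec(theta=np.pi / 6, spin_channels=1,
                                           seed=1))
        nd = compute_ndos(res.archive.P_ref, res.archive.P_cmp, res.archive.S)
        assert abs(nd.q_nd[0] - 0.5) < 1e-10
        assert abs(nd.q_nd[-1] + 0.5) < 1e-10

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DimensionMismatchError):
            compute_ndos(np.eye(4), np.eye(5), np.eye(5))

    def test_electron_count_mismatch_warns_not_raises(self):
        S = np.eye(4)
        P1 = random_idempotent_density(S, 2, seed=1)
        P2 = random_idempotent_density(S, 1, seed=2)
        with pytest.warns(UserWarning, match="electron counts differ"):
            nd = compute_ndos(P1, P2, S)
        # sum of q_nd tracks the electron difference
        assert abs(nd.q_nd.sum() - 2.0) < 1e-8

    def test_plus_minus_pairing_on_single_transfer(self):
        """Smallest q_nd is the negative of the largest on one-transfer
        fixtures (exact pairing)."""
        for seed in range(4):
            res = make_ct_pair(SyntheticCTSpec(
                theta=0.6, spin_channels=2, seed=seed,
                overlap_mode="random_spd_block"))
            nd = compute_ndos(res.archive.P_ref, res.archive.P_cmp,
                              res.archive.S)
            assert abs(nd.q_nd[0] + nd.q_nd[-1]) < 1e-10


class TestFrontierSubset:
    def test_all_below_threshold_empty(self):
        res = make_ct_pair(SyntheticCTSpec(theta=np.deg2rad(5.74),
                                           spin_channels=1, seed=0))
        nd = compute_ndos(res.archive.P_ref, res.archive.P_cmp, res.archive.S)
        assert len(nd.frontier(0.2)) == 0

    def test_reported_magnitudes_retained(self):
        # magnitudes straddling the 0.2 threshold
        from ndokit.ndo import NDOSet

        q = np.array([0.411, 0.21, -0.21, -0.411])
        nd = NDOSet(q_nd=q, vectors=np.eye(4))
        sub = nd.frontier(0.2)
        assert len(sub) == 4
        np.testing.assert_array_equal(sub.q_nd, q)
        assert len(nd.frontier(0.3)) == 2

    def test_negative_threshold_rejected(self):
        from ndokit.ndo import NDOSet

        nd = NDOSet(q_nd=np.zeros(1), vectors=np.eye(1))
        with pytest.raises(ValueError):
            nd.frontier(-0.1)


class TestInvariants:
    def test_sum_rule_matches_trace(self):
        """sum q_nd = Tr((P_ref-P_cmp) S) for arbitrary symmetric inputs."""
        for seed in range(6):
            n = 10
            S = random_spd(n, seed=seed)
            P1 = random_idempotent_density(S, 3, seed=seed + 100)
            P2 = random_idempotent_density(S, 3, seed=seed + 200)
            nd = compute_ndos(P1, P2, S)
            assert abs(nd.q_nd.sum() - np.trace((P1 - P2) @ S)) < 1e-8

    def test_spectrum_invariant_to_orthonormalization(self):
        for seed in range(5):
            n = 12
            S = random_spd(n, seed=seed)
            P1 = random_idempotent_density(S, 4, seed=seed + 10)
            P2 = random_idempotent_density(S, 4, seed=seed + 20)
            q1 = compute_ndos(P1, P2, S,
                              ortho=lowdin_orthonormalizer(S)).q_nd
            q2 = compute_ndos(P1, P2, S,
                              ortho=canonical_orthonormalizer(S)).q_nd
            np.testing.assert_allclose(np.sort(q1), np.sort(q2), atol=1e-8)

    def test_matches_bruteforce_eigensolve(self):
        """Independent oracle: explicit S^(1/2) transform + dense eigh."""
        for n in (4, 6, 8):
            S = random_spd(n, seed=n)
            P1 = random_idempotent_density(S, n // 2, seed=n + 1)
            P2 = random_idempotent_density(S, n // 2, seed=n + 2)
            Shalf = sla.fractional_matrix_power(S, 0.5).real
            q_oracle = np.sort(np.linalg.eigvalsh(
                Shalf @ (P1 - P2) @ Shalf))[::-1]
            nd = compute_ndos(P1, P2, S)
            np.testing.assert_allclose(nd.q_nd, q_oracle, atol=1e-8)


class TestDensityMatrixContracts:
    def test_validation_of_closed_shell_fixture(self):
        res = make_ct_pair(SyntheticCTSpec(theta=0.4, spin_channels=2,
                                           seed=5,
                                           overlap_mode="random_spd_block"))
        a = res.archive
        DensityMatrix(a.P_ref).validate(a.S)
        DensityMatrix(a.P_cmp).validate(a.S)
        assert abs(DensityMatrix(a.P_ref).electron_count(a.S) - 2.0) < 1e-8

    def test_asymmetric_density_rejected(self):
        M = np.array([[1.0, 0.2], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DensityMatrix(M)
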