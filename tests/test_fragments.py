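"""Fragment partitions, Mulliken attribution, donor/acceptor counting."""

import numpy as np
import pytest

from ndokit.fragments import (FragmentPartition, classify_donors_acceptors,
                              fragment_deformation_charges,
                              lowdin_orbital_populations,
                              mulliken_orbital_populations)
from ndokit.ndo import compute_ndos
from ndokit.synthetic import SyntheticCTSpec, make_ct_pair, make_multi_ct

from conftest import random_spd


class TestFragmentPartition:
    def test_one_based_round_trip_and_rest(self):
        p = FragmentPartition.from_dict({"a": [1, 2], "b": [4]}, n_atoms=5)
        assert p.names == ["a", "b", "rest"]
        assert p.atom_sets[2] == frozenset({2, 4})

    def test_overlapping_fragments_rejected(self):
        with pytest.raises(ValueError, match="reuses atoms"):
            FragmentPartition.from_dict({"a": [1, 2], "b": [2, 3]})

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError, match="1-based"):
            FragmentPartition.from_dict({"a": [0, 1]})

    def test_uncovered_atom_without_rest_rejected(self):
        p = FragmentPartition.from_dict({"a": [1]})
        with pytest.raises(ValueError, match="not covered"):
            p.fragment_of_atom(3)


class TestOrbitalPopulations:
    def test_disjoint_support_is_all_on_one_fragment(self):
        S = np.eye(6)
        part = FragmentPartition.from_dict({"A": [1, 2, 3], "B": [4, 5, 6]})
        v = np.zeros(6)
        v[1] = 1.0
        pops = mulliken_orbital_populations(v, S, part, np.arange(6))
        np.testing.assert_allclose(pops, [1.0, 0.0], atol=1e-14)

    def test_matches_bruteforce_index_sum(self):
        """Oracle: explicit loop over basis indices, fraction_F =
        sum_{mu in F} v_mu (S v)_mu."""
        res = make_ct_pair(SyntheticCTSpec(
            theta=np.pi / 6, spin_channels=1, seed=3,
            overlap_mode="random_spd_block"))
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        v = nd.vectors[:, -1]  # the negative-q NDO
        pops = mulliken_orbital_populations(v, a.S, res.partition,
                                            a.meta.atom_of_basis)
        Sv = a.S @ v
        atom_of = a.meta.atom_of_basis
        oracle = np.zeros(2)
        for mu in range(len(v)):
            frag = 0 if atom_of[mu] in res.partition.atom_sets[0] else 1
            oracle[frag] += v[mu] * Sv[mu]
        np.testing.assert_allclose(pops, oracle, atol=1e-10)
        assert abs(pops.sum() - 1.0) < 1e-10

    def test_unnormalized_vector_rejected(self):
        S = np.eye(4)
        part = FragmentPartition.from_dict({"A": [1, 2], "B": [3, 4]})
        with pytest.raises(ValueError, match="S-normalized"):
            mulliken_orbital_populations(np.ones(4), S, part, np.arange(4))

    def test_lowdin_populations_nonnegative_and_normalized(self):
        S = random_spd(6, seed=9)
        part = FragmentPartition.from_dict({"A": [1, 2, 3], "B": [4, 5, 6]})
        v = np.random.default_rng(1).normal(size=6)
        v /= np.sqrt(v @ S @ v)
        pops = lowdin_orbital_populations(v, S, part, np.arange(6))
        assert (pops > -1e-12).all()
        assert abs(pops.sum() - 1.0) < 1e-10


class TestFragmentDeformationCharges:
    def test_zero_for_equal_densities(self):
        res = make_ct_pair(SyntheticCTSpec(theta=0.0, seed=0))
        a = res.archive
        dq = fragment_deformation_charges(a.P_ref, a.P_ref, a.S,
                                          res.partition,
                                          a.meta.atom_of_basis)
        np.testing.assert_allclose(dq, 0.0, atol=1e-14)

    def test_single_channel_transfer_is_sin_squared(self):
        theta = np.pi / 6
        res = make_ct_pair(SyntheticCTSpec(theta=theta, spin_channels=1,
                                           seed=2))
        a = res.archive
        dq = fragment_deformation_charges(a.P_ref, a.P_cmp, a.S,
                                          res.partition,
                                          a.meta.atom_of_basis)
        np.testing.assert_allclose(dq, [np.sin(theta) ** 2,
                                        -np.sin(theta) ** 2], atol=1e-10)

    def test_two_disjoint_transfers_on_four_fragments(self):
        th1, th2 = 0.5, 0.9
        res = make_multi_ct([4, 3, 5, 4], [(0, 1, th1), (2, 3, th2)],
                            spin_channels=1, seed=6,
                            overlap_mode="random_spd_block")
        a = res.archive
        dq = fragment_deformation_charges(a.P_ref, a.P_cmp, a.S,
                                          res.partition,
                                          a.meta.atom_of_basis)
        expect = [np.sin(th1) ** 2, -np.sin(th1) ** 2,
                  np.sin(th2) ** 2, -np.sin(th2) ** 2]
        np.testing.assert_allclose(dq, expect, atol=1e-10)
        # brute-force trace oracle
        diag = np.einsum("ij,ji->i", a.P_ref - a.P_cmp, a.S)
        oracle = [diag[m].sum()
                  for m in res.partition.basis_masks(a.meta.atom_of_basis)]
        np.testing.assert_allclose(dq, oracle, atol=1e-12)


class TestOrbitalChargeIdentity:
    @pytest.mark.parametrize("seed", range(4))
    def test_qnd_weighted_populations_equal_delta_q(self, seed):
        """Exact identity sum_k q_k pop_F(v_k) = Delta q_F."""
        res = make_multi_ct([5, 4, 6], [(0, 1, 0.7), (0, 2, 0.3)],
                            spin_channels=2, seed=seed,
                            overlap_mode="random_spd_block")
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        dq = fragment_deformation_charges(a.P_ref, a.P_cmp, a.S,
                                          res.partition,
                                          a.meta.atom_of_basis)
        acc = np.zeros(len(res.partition))
        for k in range(len(nd)):
            acc += nd.q_nd[k] * mulliken_orbital_populations(
                nd.vectors[:, k], a.S, res.partition, a.meta.atom_of_basis)
        np.testing.assert_allclose(acc, dq, atol=1e-8)
        # charge conservation: equal electron counts -> sum exactly 0
        assert abs(dq.sum()) < 1e-8


class TestDonorAcceptorClassification:
    def test_localized_single_transfer_counts_one_each(self):
        # near-complete transfer: both NDOs localize on their fragments
        res = make_ct_pair(SyntheticCTSpec(theta=np.deg2rad(85.0),
                                           spin_channels=2, seed=4))
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        rep = classify_donors_acceptors(nd, a.S, res.partition,
                                        a.meta.atom_of_basis)
        assert (rep.n_d, rep.n_a) == (1, 1)
        assert rep.donors == ["donor"] and rep.acceptors == ["acceptor"]
        pops = rep.populations
        assert pops.iloc[0]["donor"] > 0.9
        assert pops.iloc[-1]["acceptor"] > 0.9

    def test_three_donors_into_one_acceptor(self):
        res = make_multi_ct([4, 4, 4, 8],
                            [(0, 3, 1.4), (1, 3, 1.35), (2, 3, 1.45)],
                            spin_channels=2, seed=8)
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        rep = classify_donors_acceptors(nd, a.S, res.partition,
                                        a.meta.atom_of_basis)
        assert rep.n_d == 3
        assert rep.n_a == 1
        assert rep.acceptors == ["frag3"]

    def test_bad_cutoff_rejected(self):
        res = make_ct_pair(SyntheticCTSpec(seed=0))
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError, match="membership_cutoff"):
                classify_donors_acceptors(nd, a.S, res.partition,
                                          a.meta.atom_of_basis,
                                          membership_cutoff=bad)

    def test_invariant_to_fragment_order_and_basis_permutation(self):
        res = make_ct_pair(SyntheticCTSpec(theta=np.deg2rad(80.0),
                                           spin_channels=2, seed=12,
                                           overlap_mode="random_spd_block"))
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        rep = classify_donors_acceptors(nd, a.S, res.partition,
                                        a.meta.atom_of_basis)
        # reversed fragment declaration order
        part_rev = FragmentPartition(names=list(res.partition.names[::-1]),
                                     atom_sets=list(res.partition.atom_sets[::-1]))
        rep2 = classify_donors_acceptors(nd, a.S, part_rev,
                                         a.meta.atom_of_basis)
        assert (rep.n_d, rep.n_a) == (rep2.n_d, rep2.n_a)
        assert set(rep.donors) == set(rep2.donors)
        # permute basis functions (here 1:1 with atoms): relabel both the
        # matrices and the atom map consistently
        rng = np.random.default_rng(0)
        perm = rng.permutation(a.n_basis)
        Sp = a.S[np.ix_(perm, perm)]
        P1p = a.P_ref[np.ix_(perm, perm)]
        P2p = a.P_cmp[np.ix_(perm, perm)]
        atom_of_p = a.meta.atom_of_basis[perm]
        ndp = compute_ndos(P1p, P2p, Sp)
        rep3 = classify_donors_acceptors(ndp, Sp, res.partition, atom_of_p)
        assert (rep.n_d, rep.n_a) == (rep3.n_d, rep3.n_a)
        np.testing.assert_allclose(
            rep.delta_q.to_numpy(), rep3.delta_q.to_numpy(), atol=1e-8)

    def test_report_serializes(self, tmp_path):
        res = make_ct_pair(SyntheticCTSpec(theta=1.2, spin_channels=2, seed=1))
        a = res.archive
        nd = compute_ndos(a.P_ref, a.P_cmp, a.S)
        rep = classify_donors_acceptors(nd, a.S, res.partition,
                                        a.meta.atom_of_basis)
        out = tmp_path / "dda.json"
        rep.to_json(out)
        import json

        data = json.loads(out.read_text())
        assert data["N_d"] == rep.n_d
        assert abs(sum(data["fragment_delta_q"].values())) < 1e-8
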