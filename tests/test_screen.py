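"""Non-Aufbau pair screening against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ndokit.screen import (ComparabilityError, FrontierLevels,
                           PairScreenResult, pair_gap, screen_pairs,
                           summarize_by_functional)
from ndokit.synthetic import SyntheticLevelsSpec, make_levels_table


def rec(fid, q, homo, lumo, func="lda", aa=None):
    return FrontierLevels(fragment_id=fid, charge=q, homo_ev=homo,
                          lumo_ev=lumo, functional=func, amino_acid=aa)


class TestPairGap:
    def test_anion_homo_above_cation_lumo_is_flagged(self):
        # glycine-style levels: anion HOMO +0.64 eV, cation LUMO -6.79 eV
        gly_m = rec("gly_minus", -1, 0.64, 5.72)
        gly_p = rec("gly_plus", +1, -12.59, -6.79)
        gap = pair_gap(gly_m, gly_p)
        assert gap == pytest.approx(-7.43, abs=1e-10)
        assert gap < 0.0

    def test_internal_gap_positive_not_flagged(self):
        a = rec("x", 0, -7.0, -1.0)
        assert pair_gap(a, a) == pytest.approx(6.0)

    def test_degenerate_levels_not_flagged(self):
        d = rec("d", -1, -5.0, 0.0)
        a = rec("a", +1, -9.0, -5.0)
        assert pair_gap(d, a) == 0.0  # strict inequality convention

    def test_cross_functional_comparison_refused(self):
        d = rec("d", -1, 0.0, 5.0, func="lda")
        a = rec("a", +1, -12.0, -6.0, func="b3lyp")
        with pytest.raises(ComparabilityError):
            pair_gap(d, a)
        assert pair_gap(d, a, allow_cross_functional=True) < 0

    def test_non_finite_levels_rejected(self):
        with pytest.raises(ValueError):
            rec("bad", 0, np.nan, 1.0)


def brute_force(levels, rule):
    """Independent double loop (written here, not in the package)."""
    flagged = []
    for d in levels:
        for a in levels:
            if d is a or not rule(d, a):
                continue
            if a.lumo_ev - d.homo_ev < 0:
                flagged.append((d.fragment_id, a.fragment_id))
    return flagged


class TestScreenPairs:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_tables_match_generator_truth(self, seed):
        k = int(np.random.default_rng(seed).integers(0, 60))
        records, truth = make_levels_table(
            SyntheticLevelsSpec(k=k, seed=seed))
        res = screen_pairs(records)
        assert res.total == k == truth.total
        assert res.counts.equals(truth.counts)

    def test_random_band_tables_match_bruteforce(self):
        """200 random tables: screen_pairs == O(n^2) oracle, cell by cell."""
        n_mismatch = 0
        for seed in range(200):
            spec = SyntheticLevelsSpec(
                n_species=8, seed=seed,
                k=int(seed % 13) if seed % 3 else None)
            records, truth = make_levels_table(spec)
            res = screen_pairs(records)
            rule = lambda d, a: d.species != a.species
            oracle = brute_force(records, rule)
            assert res.total == len(oracle) == truth.total
            assert res.counts.equals(truth.counts)
            assert sorted((d, a) for d, a, _ in res.flagged) == sorted(oracle)

    def test_two_records_no_negative_gap(self):
        res = screen_pairs([rec("a", 0, -8.0, -1.0, aa="A"),
                            rec("b", 0, -7.5, -0.5, aa="B")])
        assert res.total == 0

    def test_saturated_anion_to_cation_cell(self):
        """Default bands put every anion HOMO above every cation LUMO:
        the (-1, +1) cell saturates at n*(n-1) = 380 for 20 species."""
        records, truth = make_levels_table(SyntheticLevelsSpec(seed=5))
        res = screen_pairs(records)
        assert res.counts.loc[-1, 1] == 380 == 20 * 19
        assert res.counts.loc[-1, 0] == 380
        # no cell can exceed s*(s-1) under the distinct-species rule
        assert (res.counts.to_numpy() <= 380).all()
        assert res.counts.equals(truth.counts)

    def test_flagged_gaps_all_negative_and_total_consistent(self):
        records, _ = make_levels_table(SyntheticLevelsSpec(seed=2))
        res = screen_pairs(records)
        assert all(g < 0 for _, _, g in res.flagged)
        assert res.total == len(res.flagged) == res.counts.to_numpy().sum()

    def test_mixed_functionals_refused(self):
        records = [rec("a", 0, -8, -1, func="lda", aa="A"),
                   rec("b", 0, -7, -1, func="pbe", aa="B")]
        with pytest.raises(ComparabilityError):
            screen_pairs(records)

    def test_exclusion_none_counts_protonation_siblings(self):
        # same species, different charge states: skipped by default,
        # counted under 'none'
        records = [rec("gly_minus", -1, 0.6, 5.7, aa="gly"),
                   rec("gly_plus", +1, -12.6, -6.8, aa="gly")]
        assert screen_pairs(records).total == 0
        assert screen_pairs(records, exclusion="none").total == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(shift=st.floats(0.0, 10.0), seed=st.integers(0, 50))
    def test_monotonicity_under_level_shifts(self, shift, seed):
        """Raising all acceptor LUMOs (or lowering donor HOMOs) never
        increases the flagged count."""
        records, _ = make_levels_table(
            SyntheticLevelsSpec(n_species=5, seed=seed))
        base = screen_pairs(records).total
        raised = [FrontierLevels(r.fragment_id, r.charge, r.homo_ev,
                                 r.lumo_ev + shift, r.functional,
                                 r.amino_acid) for r in records]
        lowered = [FrontierLevels(r.fragment_id, r.charge, r.homo_ev - shift,
                                  r.lumo_ev, r.functional, r.amino_acid)
                   for r in records]
        assert screen_pairs(raised).total <= base
        assert screen_pairs(lowered).total <= base


class TestSummarize:
    def test_empty_map_gives_empty_table(self):
        df = summarize_by_functional({})
        assert len(df) == 0

    def test_rows_sorted_by_descending_total(self):
        r10, t10 = make_levels_table(SyntheticLevelsSpec(k=10, seed=1))
        r3, t3 = make_levels_table(SyntheticLevelsSpec(k=3, seed=2))
        df = summarize_by_functional({"lda": screen_pairs(r10),
                                     "wb97": screen_pairs(r3)})
        assert list(df["total"]) == [10, 3]
        assert list(df["functional"]) == ["lda", "wb97"]

    def test_identical_inputs_identical_rows(self):
        records, _ = make_levels_table(SyntheticLevelsSpec(seed=7))
        res = screen_pairs(records)
        df = summarize_by_functional({"f1": res, "f2": res})
        a = df[df.functional == "f1"].drop(columns="functional").reset_index(drop=True)
        b = df[df.functional == "f2"].drop(columns="functional").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
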