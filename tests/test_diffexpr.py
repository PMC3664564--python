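"""Rank statistics, exact Mann-Whitney, fold changes and the DE pass."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirpair import ConfigurationError, ExpressionDataset
from mirpair.diffexpr import (call_present, mann_whitney_p, max_rank_sum_diff,
                              rank_sum_difference, run_de, signed_fold_change)


def brute_force_exact_p(case, control):
    """Independent oracle: enumerate all rank assignments of the pooled
    values and count |R_case - E| at least as extreme as observed."""
    pooled = sorted(list(case) + list(control))
    n1, n2 = len(case), len(control)
    obs = sum(sorted(pooled).index(v) + 1 for v in case)  # tie-free inputs
    mean = n1 * (n1 + n2 + 1) / 2
    count = 0
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        if abs(sum(combo) - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / comb(n1 + n2, n1)


class TestRankSumDifference:
    def test_hand_ranked_separation(self):
        r = rank_sum_difference([5, 6, 7], [1, 2, 3])
        assert (r.rank_sum_case, r.rank_sum_control) == (15, 6)
        assert r.diff == 9 == r.max_diff
        assert r.distinct

    def test_interleaved_not_distinct(self):
        r = rank_sum_difference([1, 3], [2, 4])
        assert not r.distinct
        assert abs(r.diff) < abs(r.max_diff)

    def test_seven_vs_seven_max_is_49(self):
        assert max_rank_sum_diff(7, 7) == 49  # sum(8..14) - sum(1..7)
        r = rank_sum_difference(np.arange(8, 15), np.arange(1, 8))
        assert r.diff == 49 and r.distinct

    def test_cross_group_tie_forbids_distinctness(self):
        r = rank_sum_difference([2, 3, 4], [1, 1.5, 2])
        assert not r.distinct

    def test_empty_group_raises(self):
        with pytest.raises(ConfigurationError):
            rank_sum_difference([], [1, 2])

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=8),
           st.lists(st.integers(0, 10_000), min_size=2, max_size=8))
    @settings(max_examples=300, deadline=None)
    def test_rank_criterion_equals_overlap_criterion(self, case, control):
        """|diff| attains the directional max iff group ranges don't overlap."""
        r = rank_sum_difference(case, control)
        overlap_free = min(case) > max(control) or max(case) < min(control)
        assert r.distinct == overlap_free
        assert (r.diff == r.max_diff) == overlap_free


class TestMannWhitney:
    def test_exact_small_separation(self):
        u, p = mann_whitney_p([5, 6, 7], [1, 2, 3], mode="exact")
        assert u == 9
        assert p == pytest.approx(2 / 20)

    def test_exact_7v7_separation(self):
        _, p = mann_whitney_p(np.arange(8, 15), np.arange(1, 8), mode="exact")
        assert p == pytest.approx(2 / 3432)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_p([1, 2, 3], [1, 2, 3], mode="normal")
        assert p == 1.0

    def test_exact_with_ties_raises(self):
        with pytest.raises(ConfigurationError, match="normal"):
            mann_whitney_p([1, 2, 3], [3, 4, 5], mode="exact")

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 2), (7, 7)])
    def test_exact_matches_brute_force_enumeration(self, n1, n2, rng):
        for _ in range(20):
            vals = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
            case, control = vals[:n1], vals[n1:]
            _, p = mann_whitney_p(case, control, mode="exact")
            assert p == pytest.approx(brute_force_exact_p(case, control))

    def test_monotone_in_shift(self, rng):
        """With case = control + shift, growing the shift moves U further
        into the upper tail, so the two-sided p never increases."""
        for _ in range(10):
            control = rng.normal(size=7)
            last = None
            for shift in [0.25, 0.5, 1.0, 2.0, 4.0]:
                _, p = mann_whitney_p(control + shift, control, mode="exact")
                if last is not None:
                    assert p <= last + 1e-12
                last = p


class TestSignedFoldChange:
    @pytest.mark.parametrize("case,control,expected", [
        ([4, 4], [2, 2], 2.0),
        ([1, 1], [4, 4], -4.0),
        ([3, 3], [3, 3], 1.0),
    ])
    def test_examples(self, case, control, expected):
        assert signed_fold_change(case, control) == pytest.approx(expected)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            a = rng.uniform(0.1, 10, size=5)
            b = rng.uniform(0.1, 10, size=5)
            if np.mean(a) == np.mean(b):
                continue
            assert signed_fold_change(a, b) == pytest.approx(
                -signed_fold_change(b, a))

    def test_nonpositive_mean_raises(self):
        with pytest.raises(ConfigurationError):
            signed_fold_change([0, 0], [1, 1])


def _toy_dataset(values, groups):
    values = pd.DataFrame(values)
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    values.index = [f"f{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame({"symbol": None, "kind": "mRNA", "chrom": None,
                         "position": None}, index=values.index)
    samples = pd.DataFrame({"group": groups}, index=values.columns)
    return ExpressionDataset(values, meta, samples)


class TestPresentCall:
    def test_floor_rules(self):
        ds = _toy_dataset(
            [[100, 100, 100, 100],   # above floor everywhere
             [2, 2, 2, 2],           # below everywhere
             [100, 100, 2, 2]],      # above in the case group only
            ["case", "case", "control", "control"])
        flags = call_present(ds, floor=4.0, min_frac=0.5)
        assert flags.tolist() == [True, False, True]

    def test_degenerate_floor_all_present(self):
        ds = _toy_dataset([[1, 1], [2, 2]], ["case", "control"])
        assert call_present(ds, floor=-np.inf).sum() == 2


class TestRunDE:
    def test_noiseless_planted_fold_change(self):
        ds = _toy_dataset(
            [[8] * 7 + [4] * 7 for _ in range(2)] + [[32] * 14],
            ["case"] * 7 + ["control"] * 7)
        table, summary = run_de(ds, floor=1.0)
        assert table.loc["f0", "fold_change_signed"] == pytest.approx(2.0)
        assert table.loc["f0", "direction"] == "up"
        assert bool(table.loc["f0", "distinct"])  # noiseless separation
        assert summary["present"] == 3

    def test_null_rejection_rate_matches_exact_attained_size(self, rng):
        """At 7v7 the exact test's attained size at alpha=.05 is 130/3432
        (discreteness), which the null rejection rate must track."""
        n_feat, n_rep = 400, 30
        hits = 0
        for _ in range(n_rep):
            vals = 2.0 ** rng.normal(7, 1, size=(n_feat, 14))
            ds = _toy_dataset(vals, ["case"] * 7 + ["control"] * 7)
            _, summary = run_de(ds, floor=0.0)
            hits += summary["regulated"]
        frac = hits / (n_feat * n_rep)
        assert frac == pytest.approx(130 / 3432, abs=0.004)

    def test_planted_distinct_all_flagged(self, small_data):
        ds_tx, _, truth = small_data
        table, summary = run_de(ds_tx)
        assert table.loc[truth.distinct_ids, "distinct"].all()
        assert summary["distinct"] >= len(truth.distinct_ids)

    def test_bh_adjustment_is_more_conservative(self, small_data):
        ds_tx, _, _ = small_data
        raw, s_raw = run_de(ds_tx)
        adj, s_adj = run_de(ds_tx, adjust="bh")
        assert s_adj["regulated"] <= s_raw["regulated"]
        assert (adj["p_adj"].dropna() >= adj["p_value"].dropna() - 1e-12).all()
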