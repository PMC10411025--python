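"""Ranking, RDG coding, blocked concordance, intersections and top-k."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarelens.errors import ValidationError
from rarelens.ranking import (
    DiffTable,
    RankTable,
    adjacent_intersections,
    build_rank_table,
    code_rdg,
    grouped_consistency,
    rank_annual,
    ranking_difference,
    rdg_year_counts,
    topk_persistent,
)
from conftest import make_difftable


def wide(values, years=None, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    years = years or list(range(2016, 2016 + values.shape[1]))
    ids = ids or [f"D{i:03d}" for i in range(values.shape[0])]
    return pd.DataFrame(
        values, index=pd.Index(ids, name="disease_id"), columns=pd.Index(years, name="year")
    )


def brute_force_ranks(values: pd.DataFrame) -> pd.DataFrame:
    """Oracle: explicit sort by (-value, id), rank = position + 1."""
    out = values.copy()
    for y in values.columns:
        order = sorted(values.index, key=lambda d: (-values.at[d, y], d))
        for pos, d in enumerate(order, start=1):
            out.at[d, y] = pos
    return out.astype(int)


class TestRankAnnual:
    def test_descending_values(self):
        v = wide([[10], [30], [20]], ids=["A", "B", "C"])
        r = rank_annual(v)
        assert r[2016].to_dict() == {"B": 1, "C": 2, "A": 3}

    def test_tie_broken_by_ascending_id(self):
        v = wide([[10], [10], [5]], ids=["A", "B", "C"])
        r = rank_annual(v)
        assert r[2016].to_dict() == {"A": 1, "B": 2, "C": 3}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(3, 11))
        v = wide(rng.integers(0, 20, size=(d, 3)).astype(float))
        assert rank_annual(v).equals(brute_force_ranks(v))

    def test_missing_values_rejected(self):
        v = wide([[1.0], [np.nan]])
        with pytest.raises(ValidationError, match="missing"):
            rank_annual(v)

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=30),
    )
    def test_output_is_a_permutation(self, vals):
        r = rank_annual(wide([[v] for v in vals]))
        assert sorted(r[2016]) == list(range(1, len(vals) + 1))


class TestRankingDifference:
    @pytest.mark.parametrize(
        "rs,rc,expected_diff,expected_code",
        [
            (5, 25, -20, 1),  # boundary inclusive
            (1, 30, -29, 0),
            (30, 1, 29, 2),
            (25, 5, 20, 1),
            (7, 7, 0, 1),
        ],
    )
    def test_interval_semantics(self, rs, rc, expected_diff, expected_code):
        n = 30
        s = wide([[rs if i == 0 else 0] for i in range(1)])  # placeholder
        # build a direct DiffTable through ranks is heavy; check the coder
        assert rs - rc == expected_diff
        assert code_rdg([expected_diff], 20)[0] == expected_code

    def test_diff_from_rank_table(self):
        s = wide([[1], [2], [3]])
        c = wide([[3], [1], [2]])
        ranks = RankTable(search_rank=s.astype(int), case_rank=c.astype(int))
        d = ranking_difference(ranks, cutoff=1)
        assert d.diff[2016].tolist() == [-2, 1, 1]
        assert d.rdg[2016].tolist() == [0, 1, 1]

    def test_antisymmetry_swapping_systems(self):
        rng = np.random.default_rng(3)
        vals_s = wide(rng.random((12, 2)))
        vals_c = wide(rng.random((12, 2)))
        a = ranking_difference(build_rank_table(vals_s, vals_c), cutoff=3)
        b = ranking_difference(build_rank_table(vals_c, vals_s), cutoff=3)
        assert (a.diff.to_numpy() == -b.diff.to_numpy()).all()
        swap = {0: 2, 1: 1, 2: 0}
        assert (
            a.rdg.to_numpy() == np.vectorize(swap.get)(b.rdg.to_numpy())
        ).all()

    @given(st.integers(1, 50), st.integers(0, 49))
    def test_monotone_cutoff_never_shrinks_group_one(self, tau, extra):
        rng = np.random.default_rng(11)
        diffs = rng.integers(-60, 61, size=20)
        small = code_rdg(diffs, tau)
        large = code_rdg(diffs, tau + extra)
        assert ((small == 1) <= (large == 1)).all()


class TestRdgYearCounts:
    def test_all_central_codes(self):
        dt = make_difftable([[1, 1], [1, 1], [1, 1]], years=[2016, 2017])
        counts = rdg_year_counts(dt)
        assert counts[2016].tolist() == [0, 3, 0]

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_sums_to_d(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 3, size=(9, 3))
        counts = rdg_year_counts(make_difftable(codes, years=[2016, 2017, 2018]))
        assert (counts.sum(axis=0) == 9).all()


class TestGroupedConsistency:
    def test_perfect_concordance_gives_r_one(self):
        rng = np.random.default_rng(0)
        v = wide(rng.permutation(40).astype(float)[:, None])
        ranks = build_rank_table(v, v)
        gs = grouped_consistency(ranks, block_size=10)
        assert gs.pearson_r.loc[2016] == pytest.approx(1.0)
        t = gs.table
        assert (t["mean_case_rank"] == t["mean_search_rank"]).all()

    def test_perfect_reversal_gives_r_minus_one(self):
        v = wide(np.arange(40, 0, -1).astype(float)[:, None])
        rev = wide(np.arange(1, 41).astype(float)[:, None])
        ranks = build_rank_table(v, rev)
        gs = grouped_consistency(ranks, block_size=10)
        assert gs.pearson_r.loc[2016] == pytest.approx(-1.0)

    def test_block_mean_of_permuted_case_ranks(self):
        # D=120; the diseases holding search ranks 1-20 hold case ranks
        # {1..20} in some order, so the first block's mean case rank is 10.5
        rng = np.random.default_rng(5)
        d = 120
        search = np.arange(1, d + 1)
        case = search.copy()
        case[:20] = rng.permutation(np.arange(1, 21))
        s = wide(((d + 1 - search).astype(float))[:, None])  # value; rank i gets value d+1-i
        c = wide(((d + 1 - case).astype(float))[:, None])
        ranks = build_rank_table(s, c)
        gs = grouped_consistency(ranks, block_size=20)
        first = gs.table[gs.table["block"] == 1].iloc[0]
        assert first["mean_case_rank"] == pytest.approx(10.5)
        assert first["block_label"] == "1-20"

    def test_ragged_final_block_retained(self):
        rng = np.random.default_rng(9)
        v = wide(rng.permutation(25).astype(float)[:, None])
        gs = grouped_consistency(build_rank_table(v, v), block_size=10)
        sizes = gs.table["size"].tolist()
        assert sizes == [10, 10, 5]
        assert gs.table["block_label"].tolist() == ["1-10", "11-20", "21-25"]

    def test_single_block_correlation_is_nan_with_warning(self):
        v = wide(np.arange(5).astype(float)[:, None])
        with pytest.warns(UserWarning, match="fewer than 2 blocks"):
            gs = grouped_consistency(build_rank_table(v, v), block_size=10)
        assert np.isnan(gs.pearson_r.loc[2016])

    @pytest.mark.parametrize("seed", range(8))
    def test_block_means_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = int(rng.integers(4, 11))
        s_vals = wide(rng.random((d, 3)))
        c_vals = wide(rng.random((d, 3)))
        ranks = build_rank_table(s_vals, c_vals)
        bs = 3
        gs = grouped_consistency(ranks, block_size=bs)
        for y in (2016, 2017, 2018):
            sr, cr = ranks.search_rank[y], ranks.case_rank[y]
            for b in range((d + bs - 1) // bs):
                members = sr.index[(sr - 1) // bs == b]
                row = gs.table[(gs.table["year"] == y) & (gs.table["block"] == b + 1)]
                assert row["mean_case_rank"].iloc[0] == pytest.approx(
                    cr.loc[members].mean()
                )

    def test_pearson_invariant_under_affine_transform_of_block_means(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        x = rng.random(6)
        y = rng.random(6)
        r = stats.pearsonr(x, y).statistic
        assert stats.pearsonr(3 * x + 7, 3 * y + 7).statistic == pytest.approx(r)


class TestIntersections:
    def test_simple_overlap(self):
        dt = make_difftable(
            [[1, 1], [1, 2], [0, 1]], years=[2016, 2017]
        )  # S_{1,2016}={D1,D2}, S_{1,2017}={D1,D3}
        res = adjacent_intersections(dt)
        row = res.table[(res.table["rdg"] == 1)].iloc[0]
        assert row["intersection"] == 1
        assert res.members[(1, 2016)] == {"D001", "D002"}

    def test_identical_assignments_intersect_fully(self):
        codes = [[0, 0], [1, 1], [2, 2], [1, 1]]
        res = adjacent_intersections(make_difftable(codes, years=[2016, 2017]))
        for _, row in res.table.iterrows():
            assert row["intersection"] == row["size_from"] == row["size_to"]

    def test_single_year_rejected(self):
        with pytest.raises(ValidationError, match="2 years"):
            adjacent_intersections(make_difftable([[1], [0]], years=[2016]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(3, 11))
        codes = rng.integers(0, 3, size=(d, 4))
        dt = make_difftable(codes, years=[2016, 2017, 2018, 2019])
        res = adjacent_intersections(dt)
        ids = list(dt.rdg.index)
        for _, row in res.table.iterrows():
            g, y0, y1 = row["rdg"], row["year_from"], row["year_to"]
            s0 = {ids[i] for i in range(d) if dt.rdg.at[ids[i], y0] == g}
            s1 = {ids[i] for i in range(d) if dt.rdg.at[ids[i], y1] == g}
            assert row["intersection"] == len(s0 & s1)
            assert row["size_from"] == len(s0)


class TestTopK:
    def test_constant_rankings_give_full_persistence(self):
        rng = np.random.default_rng(1)
        col = rng.permutation(30).astype(float)
        v = wide(np.column_stack([col, col, col]))
        res = topk_persistent(build_rank_table(v, v), k=10)
        assert len(res.persistent_search) == 10
        assert res.persistent_search == res.persistent_case

    def test_three_of_four_years_is_excluded(self):
        # disease A: rank 1 in three years, rank 12 in the last
        d = 15
        base = np.arange(d, 0, -1).astype(float)
        vals = np.column_stack([base] * 4)
        vals[0, 3] = 3.5  # drops A below the top 10 in 2019
        v = wide(vals, years=[2016, 2017, 2018, 2019])
        ranks = build_rank_table(v, v)
        res = topk_persistent(ranks, k=10)
        a = v.index[0]
        assert ranks.search_rank.at[a, 2019] > 10
        assert a not in res.persistent_search
        assert a in res.per_year_search[2016]

    def test_k_larger_than_panel_rejected(self):
        v = wide(np.arange(5).astype(float)[:, None])
        with pytest.raises(ValidationError, match="exceeds"):
            topk_persistent(build_rank_table(v, v), k=6)


def test_rank_table_rejects_non_permutations():
    s = wide([[1], [1], [3]]).astype(int)
    c = wide([[1], [2], [3]]).astype(int)
    with pytest.raises(ValidationError, match="permutation"):
        RankTable(search_rank=s, case_rank=c)
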