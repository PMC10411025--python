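"""Annual rankings in two surveillance systems and their comparison.

Diseases are ranked 1..D within each year by descending patient count,
separately in the search system (search-estimated patients) and the case
system (registry counts).  The per-disease ranking difference

    delta = search_rank - case_rank

is coded into three ranking-difference groups (RDGs) by a cutoff tau:
group 0 for delta < -tau (the disease looks much bigger in search than in
the registry), group 1 for |delta| <= tau (the two systems agree to within
tau positions), group 2 for delta > tau.  The module also provides the
blocked concordance summary (mean case rank per block of ``block_size``
search ranks, with a per-year Pearson correlation), adjacent-year RDG
intersections, and top-k persistence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RankTable",
    "DiffTable",
    "GroupSummary",
    "IntersectionTable",
    "TopKResult",
    "rank_annual",
    "build_rank_table",
    "ranking_difference",
    "rdg_year_counts",
    "grouped_consistency",
    "adjacent_intersections",
    "topk_persistent",
]


def rank_annual(values: pd.DataFrame) -> pd.DataFrame:
    """Rank diseases within each year, descending by value.

    ``values`` is a wide frame (disease x year).  Rank 1 is the largest
    value; ties are broken by ascending disease_id so that every year's
    ranks are a strict permutation of 1..D.
    """
    if values.isna().any().any():
        cells = [
            (d, int(y))
            for d in values.index
            for y in values.columns
            if pd.isna(values.at[d, y])
        ]
        raise ValidationError(f"rank_annual: missing values at {cells[:10]}")
    ids = values.index.to_numpy(dtype=str)
    out = pd.DataFrame(index=values.index.copy(), columns=values.columns.copy())
    for y in values.columns:
        v = values[y].to_numpy(dtype=float)
        order = np.lexsort((ids, -v))  # primary: descending value; tie: id
        r = np.empty(len(ids), dtype=np.int64)
        r[order] = np.arange(1, len(ids) + 1)
        out[y] = r
    return out.astype(np.int64)


@dataclass
class RankTable:
    """1-based annual ranks in the search and case systems."""

    search_rank: pd.DataFrame
    case_rank: pd.DataFrame

    def __post_init__(self) -> None:
        if not (
            self.search_rank.index.equals(self.case_rank.index)
            and list(self.search_rank.columns) == list(self.case_rank.columns)
        ):
            raise ValidationError("RankTable: search and case domains differ")
        d = len(self.search_rank.index)
        for name, df in (("search", self.search_rank), ("case", self.case_rank)):
            for y in df.columns:
                col = np.sort(df[y].to_numpy())
                if not np.array_equal(col, np.arange(1, d + 1)):
                    raise ValidationError(
                        f"RankTable: {name} ranks for year {y} are not a "
                        f"permutation of 1..{d}"
                    )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.search_rank.columns)

    @property
    def n_diseases(self) -> int:
        return len(self.search_rank.index)

    def to_frame(self) -> pd.DataFrame:
        s = self.search_rank.stack()
        c = self.case_rank.stack()
        out = pd.DataFrame({"search_rank": s, "case_rank": c}).reset_index()
        out.columns = ["disease_id", "year", "search_rank", "case_rank"]
        return out.sort_values(["disease_id", "year"], ignore_index=True)


def build_rank_table(search_values: pd.DataFrame, case_values: pd.DataFrame) -> RankTable:
    """Rank both systems' patient counts into one :class:`RankTable`."""
    if not (
        search_values.index.equals(case_values.index)
        and list(search_values.columns) == list(case_values.columns)
    ):
        raise ValidationError("build_rank_table: the two systems' domains differ")
    return RankTable(
        search_rank=rank_annual(search_values), case_rank=rank_annual(case_values)
    )


@dataclass
class DiffTable:
    """Ranking differences delta and their RDG codes, with the cutoff used."""

    diff: pd.DataFrame
    rdg: pd.DataFrame
    cutoff: int

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.diff.columns)

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(self.diff.index)

    def to_frame(self) -> pd.DataFrame:
        d = self.diff.stack()
        g = self.rdg.stack()
        out = pd.DataFrame({"diff": d, "rdg": g}).reset_index()
        out.columns = ["disease_id", "year", "diff", "rdg"]
        return out.sort_values(["disease_id", "year"], ignore_index=True)


def code_rdg(diff, cutoff: int):
    """Map ranking differences to codes: 0 below -cutoff, 1 within, 2 above.

    Interval boundaries are closed at +-cutoff: a difference of exactly
    +-cutoff is code 1.
    """
    arr = np.asarray(diff)
    return np.select([arr < -cutoff, arr > cutoff], [0, 2], default=1)


def ranking_difference(ranks: RankTable, cutoff: int = 20) -> DiffTable:
    """delta = search_rank - case_rank, coded into RDG 0/1/2 by ``cutoff``."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be a positive integer")
    diff = (ranks.search_rank - ranks.case_rank).astype(np.int64)
    rdg = pd.DataFrame(
        code_rdg(diff.to_numpy(), cutoff),
        index=diff.index.copy(),
        columns=diff.columns.copy(),
        dtype=np.int64,
    )
    return DiffTable(diff=diff, rdg=rdg, cutoff=int(cutoff))


def rdg_year_counts(diffs: DiffTable) -> pd.DataFrame:
    """Number of diseases per RDG code per year (rows: codes 0,1,2)."""
    out = pd.DataFrame(
        0, index=pd.Index([0, 1, 2], name="rdg"), columns=diffs.rdg.columns.copy()
    )
    for y in diffs.rdg.columns:
        vc = diffs.rdg[y].value_counts()
        for g in (0, 1, 2):
            out.at[g, y] = int(vc.get(g, 0))
    return out


@dataclass
class GroupSummary:
    """Blocked concordance: block means and per-year Pearson correlation."""

    table: pd.DataFrame  # year, block, block_label, size, mean_search_rank, mean_case_rank
    pearson_r: pd.Series  # year -> r (NaN when < 2 blocks)
    block_size: int


def grouped_consistency(ranks: RankTable, block_size: int = 20) -> GroupSummary:
    """Concordance of the two rankings, summarised in search-rank blocks.

    Within each year, diseases are grouped into consecutive blocks of
    ``block_size`` by their search rank (1-20, 21-40, ... by default; the
    final block may be smaller when D is not a multiple).  For each block
    the mean case rank of its members is computed, and the per-year Pearson
    correlation between block mean search ranks and block mean case ranks
    quantifies how well the case ranking tracks the search ranking.
    """
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    d = ranks.n_diseases
    n_blocks = (d + block_size - 1) // block_size
    rows = []
    rs = {}
    for y in ranks.search_rank.columns:
        sr = ranks.search_rank[y]
        cr = ranks.case_rank[y]
        block_of = (sr - 1) // block_size  # 0-based block index
        mean_s = sr.groupby(block_of).mean()
        mean_c = cr.groupby(block_of).mean()
        sizes = sr.groupby(block_of).size()
        for b in range(n_blocks):
            lo = b * block_size + 1
            hi = min((b + 1) * block_size, d)
            rows.append(
                {
                    "year": int(y),
                    "block": b + 1,
                    "block_label": f"{lo}-{hi}",
                    "size": int(sizes.loc[b]),
                    "mean_search_rank": float(mean_s.loc[b]),
                    "mean_case_rank": float(mean_c.loc[b]),
                }
            )
        if n_blocks < 2:
            warnings.warn(
                f"year {y}: fewer than 2 blocks, Pearson correlation undefined",
                stacklevel=2,
            )
            rs[int(y)] = float("nan")
        else:
            x = mean_s.loc[range(n_blocks)].to_numpy()
            z = mean_c.loc[range(n_blocks)].to_numpy()
            rs[int(y)] = float(stats.pearsonr(x, z).statistic)
    table = pd.DataFrame(rows)
    pearson = pd.Series(rs, name="pearson_r")
    pearson.index.name = "year"
    return GroupSummary(table=table, pearson_r=pearson, block_size=int(block_size))


@dataclass
class IntersectionTable:
    """RDG member sets per year and their adjacent-year intersections."""

    members: dict  # (rdg code, year) -> frozenset of disease ids
    table: pd.DataFrame  # rdg, year_from, year_to, size_from, size_to, intersection


def adjacent_intersections(diffs: DiffTable) -> IntersectionTable:
    """Stability of RDG membership: |S_{g,y} ∩ S_{g,y+1}| per code and year pair."""
    years = list(diffs.years)
    if len(years) < 2:
        raise ValidationError("adjacent_intersections: need at least 2 years")
    members = {}
    for y in years:
        col = diffs.rdg[y]
        for g in (0, 1, 2):
            members[(g, y)] = frozenset(col.index[col == g])
    rows = []
    for g in (0, 1, 2):
        for y0, y1 in zip(years, years[1:]):
            s0, s1 = members[(g, y0)], members[(g, y1)]
            rows.append(
                {
                    "rdg": g,
                    "year_from": y0,
                    "year_to": y1,
                    "size_from": len(s0),
                    "size_to": len(s1),
                    "intersection": len(s0 & s1),
                }
            )
    return IntersectionTable(members=members, table=pd.DataFrame(rows))


@dataclass
class TopKResult:
    """Diseases in the top k every year, per system, plus per-year lists."""

    k: int
    persistent_search: frozenset
    persistent_case: frozenset
    per_year_search: dict  # year -> ordered list of ids, rank 1 first
    per_year_case: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for system, per_year in (
            ("search", self.per_year_search),
            ("case", self.per_year_case),
        ):
            for y, lst in per_year.items():
                for r, d in enumerate(lst, start=1):
                    rows.append(
                        {"system": system, "year": y, "rank": r, "disease_id": d}
                    )
        return pd.DataFrame(rows)


def topk_persistent(ranks: RankTable, k: int = 10) -> TopKResult:
    """Diseases ranked <= k in *every* year, for each system separately."""
    if k > ranks.n_diseases:
        raise ValidationError(f"k={k} exceeds the number of diseases")
    result = {}
    per_year_all = {}
    for name, df in (("search", ranks.search_rank), ("case", ranks.case_rank)):
        per_year = {}
        sets = []
        for y in df.columns:
            col = df[y]
            top = col[col <= k].sort_values()
            per_year[int(y)] = list(top.index)
            sets.append(frozenset(top.index))
        persistent = frozenset.intersection(*sets)
        result[name] = persistent
        per_year_all[name] = per_year
    return TopKResult(
        k=int(k),
        persistent_search=result["search"],
        persistent_case=result["case"],
        per_year_search=per_year_all["search"],
        per_year_case=per_year_all["case"],
    )
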