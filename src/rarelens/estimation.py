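"""Search popularity and search-estimated patient counts.

Search popularity of disease d in year y is the fraction of all queries
that year matching d's keywords, p_{d,y} = q_{d,y} / Q_y.  Under the
assumption that search-engine users are a random sample of the population,
multiplying popularity by the year's population P_y gives a proxy patient
count, N_hat_{d,y} = p_{d,y} * P_y.  Both quantities are scale-free in the
total query volume, which is what makes a down-sampled log usable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .errors import ComputationError, ConfigError, ValidationError
from .lexicon import AnnualCounts

__all__ = [
    "PopulationSeries",
    "EstimateTable",
    "compute_popularity",
    "estimate_patients",
]


@dataclass(frozen=True)
class PopulationSeries:
    """Persons at risk per year."""

    population: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.population, dtype=float)
        s.index = s.index.astype(int)
        if (s <= 0).any():
            bad = [int(y) for y in s.index[s <= 0]]
            raise ConfigError(f"population: non-positive value for year(s) {bad}")
        s.name = "population"
        s.index.name = "year"
        object.__setattr__(self, "population", s)

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "PopulationSeries":
        return cls(pd.Series(dict(mapping)))

    @classmethod
    def from_csv(cls, path) -> "PopulationSeries":
        df = pd.read_csv(path)
        if not {"year", "population"}.issubset(df.columns):
            raise ValidationError("population file: need columns year,population")
        return cls(pd.Series(df["population"].to_numpy(), index=df["year"].to_numpy()))

    def __getitem__(self, year: int) -> float:
        return float(self.population.loc[int(year)])


@dataclass
class EstimateTable:
    """Popularity ratios and (optionally) projected patient counts."""

    popularity: pd.DataFrame
    est_patients: Optional[pd.DataFrame] = None

    def year_totals(self) -> pd.Series:
        """Total search-estimated patients per year (reporting aid)."""
        if self.est_patients is None:
            raise ComputationError("est_patients not computed yet")
        tot = self.est_patients.sum(axis=0)
        tot.name = "est_patients_total"
        return tot

    def to_frame(self, counts: Optional[AnnualCounts] = None) -> pd.DataFrame:
        pop = self.popularity.stack()
        out = pd.DataFrame({"popularity": pop})
        if self.est_patients is not None:
            out["est_patients"] = self.est_patients.stack()
        if counts is not None:
            out.insert(0, "query_count", counts.query_count.stack())
        out = out.reset_index()
        out = out.rename(columns={"level_0": "disease_id", "level_1": "year"})
        return out.sort_values(["disease_id", "year"], ignore_index=True)


def compute_popularity(counts: AnnualCounts) -> EstimateTable:
    """p_{d,y} = q_{d,y} / Q_y for every disease-year cell."""
    for y in counts.years:
        if int(counts.total_queries.loc[y]) <= 0:
            raise ComputationError(
                f"total query volume is zero for year {y}; popularity undefined"
            )
    pop = counts.query_count.div(counts.total_queries.astype(float), axis=1)
    return EstimateTable(popularity=pop)


def estimate_patients(est: EstimateTable, pop: PopulationSeries) -> EstimateTable:
    """N_hat_{d,y} = p_{d,y} * P_y; kept as a real number, rounded only in reports."""
    years = [int(y) for y in est.popularity.columns]
    missing = [y for y in years if y not in pop.population.index]
    if missing:
        raise ConfigError(f"population: missing year(s) {missing}")
    scale = pop.population.loc[years]
    scale.index = est.popularity.columns
    patients = est.popularity.mul(scale, axis=1)
    return EstimateTable(popularity=est.popularity, est_patients=patients)
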