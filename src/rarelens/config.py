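"""Scenario and analysis configuration.

A :class:`ScenarioConfig` fully describes one synthetic study: the disease
panel, the calendar years, the population at risk, the prevalence law across
diseases, how intensely patients search, how often publicity inflates a
disease's search interest, and how completely the registry captures true
cases.  :class:`AnalysisParams` holds the knobs of the downstream analysis
(ranking-difference cutoff, block size, top-k, classification policy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigError


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic surveillance scenario.

    Attributes
    ----------
    n_diseases:
        Number of diseases in the panel (>= 2).
    years:
        Strictly increasing calendar years of the study window.
    population:
        Persons at risk per year (the population the popularity ratio is
        projected onto).
    prevalence_logmu, prevalence_logsigma:
        Parameters of the log-normal prevalence law across diseases, in
        cases per person; a large sigma gives the heavy cross-disease tail
        typical of rare-disease catalogs.
    search_rate:
        Expected queries per true patient per year.
    publicity_spike_prob:
        Per disease-year probability that outside attention (news, a film)
        inflates search interest.
    publicity_spike_scale:
        Multiplicative inflation of query volume under a spike (>= 1).
    reporting_alpha, reporting_beta:
        Beta-law parameters of the per-disease registry reporting rate,
        modelling diagnostic difficulty / under-ascertainment.
    reporting_rate:
        Optional point-mass override; when set, every disease reports this
        fixed fraction of true cases and the Beta law is ignored.
    background_queries:
        Count of non-disease noise queries emitted per year.
    seed:
        Root seed; every random stream in the generator derives from it.
    """

    n_diseases: int
    years: tuple[int, ...]
    population: dict[int, float]
    prevalence_logmu: float
    prevalence_logsigma: float
    search_rate: float
    publicity_spike_prob: float
    publicity_spike_scale: float
    reporting_alpha: float
    reporting_beta: float
    background_queries: dict[int, int]
    seed: int = 0
    reporting_rate: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(
            self, "population", {int(y): float(p) for y, p in self.population.items()}
        )
        object.__setattr__(
            self,
            "background_queries",
            {int(y): int(c) for y, c in self.background_queries.items()},
        )
        self.validate()

    def validate(self) -> None:
        _require(self.n_diseases >= 2, "n_diseases", "must be >= 2")
        _require(len(self.years) >= 1, "years", "must be non-empty")
        _require(
            all(a < b for a, b in zip(self.years, self.years[1:])),
            "years",
            "must be strictly increasing",
        )
        for y in self.years:
            _require(y in self.population, "population", f"missing year {y}")
            _require(self.population[y] > 0, "population", f"year {y} must be > 0")
            _require(
                y in self.background_queries, "background_queries", f"missing year {y}"
            )
            _require(
                self.background_queries[y] >= 0,
                "background_queries",
                f"year {y} must be >= 0",
            )
        _require(self.prevalence_logsigma >= 0, "prevalence_logsigma", "must be >= 0")
        _require(self.search_rate >= 0, "search_rate", "must be >= 0")
        _require(
            0.0 <= self.publicity_spike_prob <= 1.0,
            "publicity_spike_prob",
            "must be in [0, 1]",
        )
        _require(
            self.publicity_spike_scale >= 1.0,
            "publicity_spike_scale",
            "must be >= 1",
        )
        _require(self.reporting_alpha > 0, "reporting_alpha", "must be > 0")
        _require(self.reporting_beta > 0, "reporting_beta", "must be > 0")
        if self.reporting_rate is not None:
            _require(
                0.0 <= self.reporting_rate <= 1.0,
                "reporting_rate",
                "must be in [0, 1]",
            )
        _require(int(self.seed) == self.seed, "seed", "must be an integer")

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("scenario file: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"scenario file: unknown fields {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:  # missing required field
            raise ConfigError(f"scenario file: {exc}") from exc


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the ranking comparison and classification.

    ``cutoff`` is the half-width tau of the central ranking-difference
    interval [-tau, tau] coded as group 1; ``block_size`` the number of
    diseases per search-rank block in the concordance summary; ``top_k``
    the depth of the persistence analysis; ``baseline_year`` the year whose
    ranking-difference group defines the disease grouping in the GLM
    (default: earliest year); ``classify_policy`` how the per-year codes
    are collapsed to one code per disease.
    """

    cutoff: int = 20
    block_size: int = 20
    top_k: int = 10
    baseline_year: Optional[int] = None
    classify_policy: str = "majority"
    match_mode: str = "substring"

    def __post_init__(self) -> None:
        _require(self.cutoff > 0, "cutoff", "must be a positive integer")
        _require(self.block_size >= 1, "block_size", "must be >= 1")
        _require(self.top_k >= 1, "top_k", "must be >= 1")
        _require(
            self.classify_policy in ("majority", "baseline-year"),
            "classify_policy",
            "must be 'majority' or 'baseline-year'",
        )
        _require(
            self.match_mode in ("substring", "exact"),
            "match_mode",
            "must be 'substring' or 'exact'",
        )


def default_scenario(seed: int = 2016) -> ScenarioConfig:
    """The packaged default scenario.

    A 120-disease panel observed 2016-2019 over a 10-million-person panel
    population (the method is scale-free in the population, so a panel of
    this size preserves the ranking structure at desk-scale run times).
    Prevalence is log-normal with a heavy cross-disease tail; the registry
    captures on average ~30% of true cases with wide per-disease spread;
    one disease-year in ten receives a six-fold publicity spike.
    """
    years = (2016, 2017, 2018, 2019)
    pop = {2016: 9.90e6, 2017: 9.95e6, 2018: 1.000e7, 2019: 1.005e7}
    return ScenarioConfig(
        n_diseases=120,
        years=years,
        population=pop,
        prevalence_logmu=-11.51,  # median prevalence ~1e-5 cases/person
        prevalence_logsigma=1.6,
        search_rate=2.0,
        publicity_spike_prob=0.10,
        publicity_spike_scale=6.0,
        reporting_alpha=1.5,
        reporting_beta=3.5,
        background_queries={y: 100_000 for y in years},
        seed=seed,
    )
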