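"""Seeded synthetic search logs, case registries and lexicons.

The real data sources this package targets — a commercial search engine's
query logs and a national rare-disease registry — are not publicly
available, so the generator produces stand-ins with the statistical
structure the analysis assumes:

* per-disease prevalence drawn from a heavy-tailed log-normal law, giving
  true patient counts ``T_{d,y} = round(prevalence_d * population_y)``;
* query volume proportional to patients, ``qbar_{d,y} = search_rate *
  T_{d,y} * pi_{d,y}``, where the publicity multiplier ``pi`` is 1 except
  in randomly drawn spike disease-years (news coverage, a film);
* registry counts thinned by a per-disease reporting rate ``rho_d`` drawn
  from a Beta law (diagnostic difficulty), ``Cbar_{d,y} = rho_d * T_{d,y}``;
* emitted files with Poisson query counts and Binomial reported counts
  around those expectations, plus non-matching background queries.

All random streams derive from the single scenario seed through fixed
spawn keys, so adding a new stream never perturbs the existing ones.  The
noise-free expectations, together with the ranking-difference groups and
categories they imply, are exposed as a ground-truth oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .errors import ValidationError
from .lexicon import DiseaseEntry, Lexicon
from .ranking import build_rank_table, ranking_difference

__all__ = [
    "SyntheticTruth",
    "LogSummary",
    "RegistrySummary",
    "generate_truth",
    "generate_lexicon",
    "emit_search_log",
    "emit_case_registry",
]

# fixed sub-stream spawn keys; append-only so streams stay stable
_STREAMS = {
    "prevalence": 0,
    "publicity": 1,
    "reporting": 2,
    "lexicon": 3,
    "search_log": 4,
    "registry": 5,
}


def _rng(config: ScenarioConfig, stream: str) -> np.random.Generator:
    key = _STREAMS[stream]
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def _disease_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"RD{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class SyntheticTruth:
    """Generator parameters, noise-free expectations and derived ground truth.

    ``truth_rdg`` is the ranking-difference group table obtained by running
    the ranking comparison on the noise-free expected counts; the
    ``truth_category`` per disease applies the classification rule to the
    baseline (first) year's code.
    """

    config: ScenarioConfig
    prevalence: pd.Series  # disease -> cases per person
    true_patients: pd.DataFrame  # disease x year, integer T
    publicity: pd.DataFrame  # disease x year, multiplier >= 1
    reporting_rate: pd.Series  # disease -> rho in [0, 1]
    expected_query_count: pd.DataFrame  # disease x year, real qbar
    expected_case_count: pd.DataFrame  # disease x year, real Cbar
    truth_rdg: pd.DataFrame  # disease x year in {0,1,2}
    truth_category: pd.Series  # disease -> {1,2}

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(self.prevalence.index)


def generate_truth(config: ScenarioConfig, cutoff: int = 20) -> SyntheticTruth:
    """Draw disease-level parameters and derive all noise-free expectations.

    Deterministic for a fixed seed.  ``cutoff`` is the ranking-difference
    half-width used when deriving the ground-truth RDG table.
    """
    ids = _disease_ids(config.n_diseases)
    years = list(config.years)
    idx = pd.Index(ids, name="disease_id")
    cols = pd.Index(years, name="year")

    prevalence = pd.Series(
        np.exp(
            _rng(config, "prevalence").normal(
                config.prevalence_logmu, config.prevalence_logsigma, len(ids)
            )
        ),
        index=idx,
        name="prevalence",
    )
    pop = np.array([config.population[y] for y in years])
    true_patients = pd.DataFrame(
        np.rint(np.outer(prevalence.to_numpy(), pop)).astype(np.int64),
        index=idx,
        columns=cols,
    )

    spike_rng = _rng(config, "publicity")
    spikes = spike_rng.random((len(ids), len(years))) < config.publicity_spike_prob
    publicity = pd.DataFrame(
        np.where(spikes, config.publicity_spike_scale, 1.0), index=idx, columns=cols
    )

    if config.reporting_rate is not None:
        rho = np.full(len(ids), float(config.reporting_rate))
    else:
        rho = _rng(config, "reporting").beta(
            config.reporting_alpha, config.reporting_beta, len(ids)
        )
    reporting_rate = pd.Series(rho, index=idx, name="reporting_rate")

    expected_query = config.search_rate * true_patients * publicity
    expected_case = true_patients.mul(reporting_rate, axis=0)

    ranks = build_rank_table(expected_query, expected_case)
    diffs = ranking_difference(ranks, cutoff=cutoff)
    truth_rdg = diffs.rdg
    baseline = truth_rdg[years[0]]
    truth_category = pd.Series(
        np.where(baseline == 0, 2, 1), index=idx, dtype=int, name="category"
    )

    return SyntheticTruth(
        config=config,
        prevalence=prevalence,
        true_patients=true_patients,
        publicity=publicity,
        reporting_rate=reporting_rate,
        expected_query_count=expected_query,
        expected_case_count=expected_case,
        truth_rdg=truth_rdg,
        truth_category=truth_category,
    )


def generate_lexicon(
    config: ScenarioConfig, extra_excluded: int = 0
) -> list[DiseaseEntry]:
    """Synthetic lexicon matching :func:`generate_truth`'s disease ids.

    Each disease gets a unique alphanumeric stem and three keywords built
    on it (the stem, a "morbus" form, a "syndrome" form), so keywords of
    different diseases can never collide as substrings.  ``extra_excluded``
    appends that many entries flagged excluded, to exercise catalog
    filtering.
    """
    ids = _disease_ids(config.n_diseases)
    width = max(3, len(str(config.n_diseases)))
    entries = []
    for i, did in enumerate(ids, start=1):
        stem = f"rd{i:0{width}d}x"
        entries.append(
            DiseaseEntry(
                disease_id=did,
                canonical_name=f"Synthetic disease {i}",
                keywords=(stem, f"morbus {stem}", f"{stem} syndrome"),
                excluded=False,
            )
        )
    for j in range(1, extra_excluded + 1):
        stem = f"xrd{j:0{width}d}z"
        entries.append(
            DiseaseEntry(
                disease_id=f"XRD{j:0{width}d}",
                canonical_name=f"Excluded synthetic disease {j}",
                keywords=(stem, f"{stem} syndrome"),
                excluded=True,
            )
        )
    return entries


_QUERY_TEMPLATES = (
    "{kw}",
    "{kw} symptoms",
    "what is {kw}",
    "{kw} treatment",
    "causes of {kw}",
)

_BACKGROUND_WORDS = (
    "weather", "recipe", "football", "news", "movie", "tickets", "train",
    "schedule", "hotel", "flights", "music", "video", "shopping", "phone",
    "camera", "travel", "stocks", "games", "novel", "translation",
)


@dataclass
class LogSummary:
    """What :func:`emit_search_log` wrote: exact drawn counts per cell."""

    drawn_counts: pd.DataFrame  # disease x year matching-line counts
    lines_per_year: pd.Series
    path: str


def emit_search_log(
    truth: SyntheticTruth,
    config: ScenarioConfig,
    lexicon_entries: Sequence[DiseaseEntry],
    path,
) -> LogSummary:
    """Write a year-tagged query-log TSV around the expected query counts.

    Per disease-year, ``Poisson(qbar_{d,y})`` matching lines are emitted,
    each embedding exactly one of the disease's keywords in a query
    template; ``background_queries[y]`` non-matching noise lines are added
    and the year's lines are shuffled.  Background candidates are screened
    against the lexicon so they can never match, whatever the keywords.
    A ``.gz`` suffix on ``path`` writes gzip.
    """
    lex = Lexicon([e for e in lexicon_entries if not e.excluded])
    missing = set(truth.disease_ids) - set(lex.disease_ids)
    if missing:
        raise ValidationError(
            f"lexicon lacks entries for disease(s) {sorted(missing)[:5]}"
        )
    kw_by_id = {e.disease_id: e.keywords for e in lex}
    rng = _rng(config, "search_log")
    years = list(config.years)
    ids = list(truth.disease_ids)
    drawn = pd.DataFrame(
        0, index=truth.expected_query_count.index.copy(), columns=truth.expected_query_count.columns.copy(), dtype=np.int64
    )
    lines_per_year = {}

    from .lexicon import _open_text  # noqa: F401  (suffix handling mirrors reader)
    import gzip as _gzip

    opener = (
        (lambda p: _gzip.open(p, "wt", encoding="utf-8"))
        if str(path).endswith(".gz")
        else (lambda p: open(p, "w", encoding="utf-8"))
    )
    with opener(str(path)) as fh:
        for y in years:
            lines: list[str] = []
            for d in ids:
                qbar = float(truth.expected_query_count.at[d, y])
                n = int(rng.poisson(qbar)) if qbar > 0 else 0
                drawn.at[d, y] = n
                if n == 0:
                    continue
                kws = kw_by_id[d]
                kw_idx = rng.integers(0, len(kws), n)
                tpl_idx = rng.integers(0, len(_QUERY_TEMPLATES), n)
                lines.extend(
                    _QUERY_TEMPLATES[t].format(kw=kws[k])
                    for k, t in zip(kw_idx, tpl_idx)
                )
            n_bg = config.background_queries[y]
            if n_bg:
                lines.extend(_background_lines(lex, rng, n_bg))
            order = rng.permutation(len(lines))
            fh.write("".join(f"{y}\t{lines[i]}\n" for i in order))
            lines_per_year[y] = len(lines)
    return LogSummary(
        drawn_counts=drawn,
        lines_per_year=pd.Series(lines_per_year, name="lines"),
        path=str(path),
    )


def _background_lines(lex: Lexicon, rng: np.random.Generator, n: int) -> list[str]:
    """Noise queries guaranteed not to match any lexicon keyword."""
    out: list[str] = []
    words = _BACKGROUND_WORDS
    while len(out) < n:
        batch = n - len(out)
        k = rng.integers(2, 5, batch)
        picks = rng.integers(0, len(words), (batch, 4))
        for row, kk in zip(picks, k):
            text = " ".join(words[j] for j in row[:kk])
            if lex.match(text):  # screened out; cannot happen with digit-free words
                continue
            out.append(text)
    return out


@dataclass
class RegistrySummary:
    """What :func:`emit_case_registry` wrote."""

    drawn_counts: pd.DataFrame  # disease x year reported counts
    path: str


def emit_case_registry(
    truth: SyntheticTruth, config: ScenarioConfig, path
) -> RegistrySummary:
    """Write the case-registry CSV with Binomial(T, rho) reported counts."""
    rng = _rng(config, "registry")
    t = truth.true_patients.to_numpy()
    rho = truth.reporting_rate.to_numpy()[:, None]
    drawn = rng.binomial(t, np.broadcast_to(rho, t.shape))
    drawn_df = pd.DataFrame(
        drawn, index=truth.true_patients.index.copy(), columns=truth.true_patients.columns.copy(), dtype=np.int64
    )
    long = drawn_df.stack().reset_index()
    long.columns = ["disease_id", "year", "reported_cases"]
    long = long.sort_values(["disease_id", "year"], ignore_index=True)
    long.to_csv(str(path), index=False)
    return RegistrySummary(drawn_counts=drawn_df, path=str(path))
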