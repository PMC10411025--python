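"""Disease keyword lexicon and query-log tallying.

A lexicon maps each disease to the keywords (names, synonyms, aliases,
English names) under which its patients search.  Queries are matched by
normalized substring containment: a query counts for a disease when any of
the disease's normalized keywords occurs contiguously inside the normalized
query text.  An exact-equality mode is available for sensitivity analysis.

Matching is the hot loop of the pipeline — a year of search logs is
streamed line by line — so the lexicon pre-compiles a prefix-tree regular
expression over all keywords as a fast rejection filter; only lines that
contain at least one keyword pay for the exact per-disease scan.
"""

from __future__ import annotations

import gzip
import json
import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DiseaseEntry",
    "Lexicon",
    "AnnualCounts",
    "TallyReport",
    "normalize",
    "load_lexicon",
    "write_lexicon",
    "match_query",
    "tally_queries",
    "load_registry",
]


def normalize(text: str) -> str:
    """Normalize query/keyword text: NFKC, casefold, collapse whitespace."""
    t = unicodedata.normalize("NFKC", text).casefold()
    return " ".join(t.split())


@dataclass(frozen=True)
class DiseaseEntry:
    """One lexicon record: a disease and its matchable keywords."""

    disease_id: str
    canonical_name: str
    keywords: tuple[str, ...]
    excluded: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "keywords", tuple(self.keywords))
        if not self.keywords:
            raise ValidationError(
                f"disease {self.disease_id!r}: keyword list is empty"
            )


def _trie_pattern(words: Sequence[str]) -> str:
    """Build a prefix-tree regex matching any of ``words``.

    Equivalent to a plain alternation but with shared prefixes factored
    out, which keeps ``re.search`` close to linear in the line length even
    for lexicons with hundreds of keywords.
    """
    trie: dict = {}
    for w in words:
        node = trie
        for ch in w:
            node = node.setdefault(ch, {})
        node[""] = {}  # terminal marker

    def build(node: dict) -> str:
        terminal = "" in node
        alts = []
        for ch in sorted(k for k in node if k != ""):
            sub = build(node[ch])
            alts.append(re.escape(ch) + sub)
        if not alts:
            return ""
        if len(alts) == 1:
            body = alts[0]
            if terminal:
                return f"(?:{body})?"
            return body
        body = "(?:" + "|".join(alts) + ")"
        return body + ("?" if terminal else "")

    return build(trie)


class Lexicon:
    """An immutable set of active :class:`DiseaseEntry` with a compiled matcher.

    Keywords are normalized and de-duplicated per entry at construction.
    Matching is invariant to the order of entries and to duplicate keywords
    within an entry.
    """

    def __init__(self, entries: Iterable[DiseaseEntry]):
        entries = list(entries)
        seen: set[str] = set()
        for e in entries:
            if e.disease_id in seen:
                raise ValidationError(f"duplicate disease_id {e.disease_id!r}")
            seen.add(e.disease_id)
        norm_entries = []
        kw_to_ids: dict[str, set[str]] = {}
        for e in entries:
            kws = []
            for kw in e.keywords:
                nk = normalize(kw)
                if not nk:
                    raise ValidationError(
                        f"disease {e.disease_id!r}: keyword {kw!r} is blank "
                        "after normalization"
                    )
                if nk not in kws:
                    kws.append(nk)
            norm_entries.append(
                DiseaseEntry(e.disease_id, e.canonical_name, tuple(kws), e.excluded)
            )
            for nk in kws:
                kw_to_ids.setdefault(nk, set()).add(e.disease_id)
        self.entries: tuple[DiseaseEntry, ...] = tuple(
            sorted(norm_entries, key=lambda e: e.disease_id)
        )
        # sorted for deterministic iteration; frozensets for cheap updates
        self._kw_items: tuple[tuple[str, frozenset[str]], ...] = tuple(
            (kw, frozenset(ids)) for kw, ids in sorted(kw_to_ids.items())
        )
        self._exact: dict[str, frozenset[str]] = {
            kw: ids for kw, ids in self._kw_items
        }
        self._prefilter = re.compile(_trie_pattern([kw for kw, _ in self._kw_items]))

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(e.disease_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DiseaseEntry]:
        return iter(self.entries)

    def match(self, text: str, mode: str = "substring") -> frozenset[str]:
        """Disease ids whose keywords occur in ``text`` (already raw)."""
        norm = normalize(text)
        if not norm:
            return frozenset()
        if mode == "exact":
            return self._exact.get(norm, frozenset())
        if self._prefilter.search(norm) is None:
            return frozenset()
        hits: set[str] = set()
        for kw, ids in self._kw_items:
            if kw in norm:
                hits.update(ids)
        return frozenset(hits)


@dataclass
class LexiconReport:
    """What :func:`load_lexicon` dropped and kept."""

    n_total: int
    n_active: int
    dropped_ids: tuple[str, ...]


def load_lexicon(path) -> tuple[Lexicon, LexiconReport]:
    """Load a lexicon JSON file, dropping entries flagged ``excluded``.

    The file is an array of objects with keys ``disease_id``,
    ``canonical_name``, ``keywords`` and optional ``excluded``.  Entries
    flagged excluded are dropped (the exclusion report lists them); this is
    how a catalog entry whose definition overlaps a common disease is kept
    out of the analysis while remaining in the source file.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValidationError("lexicon file: expected a JSON array of entries")
    entries = []
    for i, obj in enumerate(raw):
        if not isinstance(obj, dict):
            raise ValidationError(f"lexicon entry {i}: expected an object")
        missing = {"disease_id", "canonical_name", "keywords"} - set(obj)
        if missing:
            raise ValidationError(f"lexicon entry {i}: missing fields {sorted(missing)}")
        entries.append(
            DiseaseEntry(
                disease_id=str(obj["disease_id"]),
                canonical_name=str(obj["canonical_name"]),
                keywords=tuple(str(k) for k in obj["keywords"]),
                excluded=bool(obj.get("excluded", False)),
            )
        )
    ids = [e.disease_id for e in entries]
    if len(ids) != len(set(ids)):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise ValidationError(f"duplicate disease_id {dupes}")
    dropped = tuple(e.disease_id for e in entries if e.excluded)
    active = [e for e in entries if not e.excluded]
    lex = Lexicon(active)
    return lex, LexiconReport(
        n_total=len(entries), n_active=len(lex), dropped_ids=dropped
    )


def write_lexicon(entries: Iterable[DiseaseEntry], path) -> None:
    payload = [
        {
            "disease_id": e.disease_id,
            "canonical_name": e.canonical_name,
            "keywords": list(e.keywords),
            "excluded": e.excluded,
        }
        for e in entries
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)


def match_query(text: str, lexicon: Lexicon, mode: str = "substring") -> frozenset[str]:
    """Set of disease ids whose keywords occur in the query text."""
    return lexicon.match(text, mode=mode)


@dataclass
class AnnualCounts:
    """Per-disease per-year query and case counts, plus total query volume.

    ``query_count`` and ``case_count`` are wide frames (disease x year,
    zero-filled); ``total_queries`` the total number of log lines per year,
    matching or not — the denominator of search popularity.
    """

    query_count: pd.DataFrame
    total_queries: pd.Series
    case_count: pd.DataFrame

    def __post_init__(self) -> None:
        qy = list(self.query_count.columns)
        if list(self.case_count.columns) != qy or list(self.total_queries.index) != qy:
            raise ValidationError("AnnualCounts: year axes differ across tables")
        if not self.query_count.index.equals(self.case_count.index):
            raise ValidationError("AnnualCounts: disease axes differ across tables")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.query_count.columns)

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(self.query_count.index)

    def to_frame(self) -> pd.DataFrame:
        """Long form: disease_id, year, query_count, case_count."""
        q = self.query_count.stack()
        c = self.case_count.stack()
        out = pd.DataFrame({"query_count": q, "case_count": c}).reset_index()
        out.columns = ["disease_id", "year", "query_count", "case_count"]
        return out.sort_values(["disease_id", "year"], ignore_index=True)


@dataclass
class TallyReport:
    lines_per_year: dict[int, int]
    malformed_lines: int
    out_of_range_lines: int
    unknown_registry_ids: tuple[str, ...]


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt", encoding="utf-8")
    return open(p, encoding="utf-8")


def load_registry(
    path, lexicon: Lexicon, years: Sequence[int]
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Read the case-registry CSV into a zero-filled wide frame.

    Rows whose disease_id is not in the lexicon are skipped with a warning;
    rows outside ``years`` are dropped silently (they are out of the study
    window by construction).
    """
    reg = pd.read_csv(path)
    required = {"disease_id", "year", "reported_cases"}
    if not required.issubset(reg.columns):
        raise ValidationError(
            f"registry file: missing columns {sorted(required - set(reg.columns))}"
        )
    known = set(lexicon.disease_ids)
    unknown = tuple(sorted(set(reg["disease_id"].astype(str)) - known))
    if unknown:
        warnings.warn(
            f"registry: skipping {len(unknown)} unknown disease id(s): "
            f"{list(unknown)[:5]}...",
            stacklevel=2,
        )
    reg = reg[reg["disease_id"].astype(str).isin(known)]
    reg = reg[reg["year"].astype(int).isin([int(y) for y in years])]
    wide = (
        reg.pivot_table(
            index="disease_id", columns="year", values="reported_cases", aggfunc="sum"
        )
        .reindex(index=sorted(known), columns=[int(y) for y in years])
        .fillna(0)
        .astype(int)
    )
    wide.index.name = "disease_id"
    wide.columns.name = "year"
    return wide, unknown


def tally_queries(
    log: Union[str, "os.PathLike", Iterable[str]],
    lexicon: Lexicon,
    registry,
    years: Sequence[int],
    mode: str = "substring",
) -> tuple[AnnualCounts, TallyReport]:
    """Stream a query log once and tally per-disease per-year query counts.

    ``log`` is a TSV path (optionally gzipped) or an iterable of
    ``"year\\tquery"`` lines.  Every parseable line in a study year
    increments the year's total; a line additionally increments the count
    of every disease whose keyword it contains (a multi-disease query
    counts once per matched disease but once in the total).  ``registry``
    is the case-counts CSV path, or ``None`` to leave cases zero-filled.
    Memory use is independent of log length.
    """
    years = [int(y) for y in years]
    yearset = set(years)
    ids = sorted(lexicon.disease_ids)
    id_pos = {d: i for i, d in enumerate(ids)}
    q = {y: np.zeros(len(ids), dtype=np.int64) for y in years}
    totals = {y: 0 for y in years}
    malformed = 0
    out_of_range = 0

    if isinstance(log, (str, bytes)) or hasattr(log, "__fspath__"):
        fh = _open_text(log)
        close = True
    else:
        fh = log
        close = False
    try:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            year_s, sep, text = line.partition("\t")
            if not sep:
                malformed += 1
                continue
            try:
                y = int(year_s)
            except ValueError:
                malformed += 1
                continue
            if y not in yearset:
                out_of_range += 1
                continue
            totals[y] += 1
            hits = lexicon.match(text, mode=mode)
            if hits:
                row = q[y]
                for d in hits:
                    row[id_pos[d]] += 1
    finally:
        if close:
            fh.close()
    if malformed:
        warnings.warn(f"query log: skipped {malformed} malformed line(s)", stacklevel=2)

    query_count = pd.DataFrame({y: q[y] for y in years}, index=pd.Index(ids, name="disease_id"))
    query_count.columns.name = "year"
    total_queries = pd.Series(totals, name="total_queries")
    total_queries.index.name = "year"

    unknown: tuple[str, ...] = ()
    if registry is not None:
        case_count, unknown = load_registry(registry, lexicon, years)
    else:
        case_count = pd.DataFrame(
            0, index=query_count.index.copy(), columns=query_count.columns.copy()
        )
    counts = AnnualCounts(
        query_count=query_count, total_queries=total_queries, case_count=case_count
    )
    report = TallyReport(
        lines_per_year={y: totals[y] for y in years},
        malformed_lines=malformed,
        out_of_range_lines=out_of_range,
        unknown_registry_ids=unknown,
    )
    return counts, report
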