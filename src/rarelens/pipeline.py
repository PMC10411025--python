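"""End-to-end orchestration: simulate -> match -> estimate -> compare -> GLM -> classify.

``run_pipeline`` executes the whole analysis on a synthetic scenario and
writes every artifact as CSV/JSON under an output directory, with the
emitted inputs (query log, registry, lexicon, population) kept alongside
so a run is fully reproducible from its own output tree.  All writes are
deterministic for a fixed configuration: re-running the same config
produces byte-identical files.
"""

from __future__ import annotations

import contextlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import AnalysisParams, ScenarioConfig
from .errors import PipelineError
from .estimation import EstimateTable, PopulationSeries, compute_popularity, estimate_patients
from .glm import Classification, GLMFit, build_design, classify_diseases, fit_glm
from .lexicon import AnnualCounts, Lexicon, load_lexicon, tally_queries, write_lexicon
from .ranking import (
    DiffTable,
    GroupSummary,
    IntersectionTable,
    RankTable,
    TopKResult,
    adjacent_intersections,
    build_rank_table,
    grouped_consistency,
    ranking_difference,
    rdg_year_counts,
    topk_persistent,
)
from .synthetic import (
    SyntheticTruth,
    emit_case_registry,
    emit_search_log,
    generate_lexicon,
    generate_truth,
)

__all__ = ["PipelineResult", "run_pipeline", "analyse_counts"]

_FLOAT_FMT = "%.10g"


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}': {exc}") from exc


@dataclass
class PipelineResult:
    """Every table the pipeline produced, plus where it was written."""

    scenario: ScenarioConfig
    params: AnalysisParams
    truth: SyntheticTruth
    counts: AnnualCounts
    estimates: EstimateTable
    ranks: RankTable
    diffs: DiffTable
    rdg_counts: pd.DataFrame
    groups: GroupSummary
    intersections: IntersectionTable
    topk: TopKResult
    glm_fit: GLMFit
    classification: Classification
    outdir: Path
    summary: dict


def analyse_counts(
    counts: AnnualCounts, pop: PopulationSeries, params: AnalysisParams
):
    """The analysis core shared by live runs and noise-free oracle checks.

    Returns (estimates, ranks, diffs, rdg_counts, groups, intersections,
    topk, glm_fit, classification).
    """
    est = estimate_patients(compute_popularity(counts), pop)
    ranks = build_rank_table(est.est_patients, counts.case_count)
    diffs = ranking_difference(ranks, cutoff=params.cutoff)
    counts_by_year = rdg_year_counts(diffs)
    groups = grouped_consistency(ranks, block_size=params.block_size)
    inter = adjacent_intersections(diffs)
    topk = topk_persistent(ranks, k=params.top_k)
    design = build_design(diffs, baseline_year=params.baseline_year)
    fit = fit_glm(design)
    cls = classify_diseases(diffs, policy=params.classify_policy)
    return est, ranks, diffs, counts_by_year, groups, inter, topk, fit, cls


def run_pipeline(
    scenario: ScenarioConfig,
    outdir,
    params: Optional[AnalysisParams] = None,
) -> PipelineResult:
    """Run the full synthetic study and write all artifacts under ``outdir``."""
    params = params or AnalysisParams()
    outdir = Path(outdir)
    inputs = outdir / "inputs"

    with _stage("simulate"):
        inputs.mkdir(parents=True, exist_ok=True)
        truth = generate_truth(scenario, cutoff=params.cutoff)
        entries = generate_lexicon(scenario)
        lex_path = inputs / "lexicon.json"
        write_lexicon(entries, lex_path)
        log_path = inputs / "queries.tsv"
        log_summary = emit_search_log(truth, scenario, entries, log_path)
        reg_path = inputs / "registry.csv"
        emit_case_registry(truth, scenario, reg_path)
        scenario.to_yaml(inputs / "scenario.yaml")
        pop = PopulationSeries.from_mapping(scenario.population)
        pop.population.to_csv(inputs / "population.csv", float_format=_FLOAT_FMT)

    with _stage("match"):
        lexicon, lex_report = load_lexicon(lex_path)
        counts, tally_report = tally_queries(
            log_path, lexicon, reg_path, scenario.years, mode=params.match_mode
        )

    with _stage("analyse"):
        est, ranks, diffs, counts_by_year, groups, inter, topk, fit, cls = (
            analyse_counts(counts, pop, params)
        )

    with _stage("write"):
        _write_outputs(
            outdir, counts, est, ranks, diffs, counts_by_year, groups, inter, topk,
            fit, cls,
        )
        rdg1_pct = {
            int(y): 100.0 * counts_by_year.at[1, y] / len(counts.disease_ids)
            for y in counts_by_year.columns
        }
        summary = {
            "package_version": __version__,
            "seed": scenario.seed,
            "n_diseases": len(counts.disease_ids),
            "years": list(scenario.years),
            "lines_per_year": {int(k): int(v) for k, v in tally_report.lines_per_year.items()},
            "est_patient_totals": {
                int(y): float(v) for y, v in est.year_totals().items()
            },
            "reported_case_totals": {
                int(y): int(v) for y, v in counts.case_count.sum(axis=0).items()
            },
            "rdg_counts": {
                int(y): [int(counts_by_year.at[g, y]) for g in (0, 1, 2)]
                for y in counts_by_year.columns
            },
            "rdg1_percent": rdg1_pct,
            "rdg1_percent_min": min(rdg1_pct.values()),
            "pearson_r": {int(y): float(v) for y, v in groups.pearson_r.items()},
            "topk_persistent_search": sorted(topk.persistent_search),
            "topk_persistent_case": sorted(topk.persistent_case),
            "category_counts": {
                int(c): int(n) for c, n in cls.category.value_counts().items()
            },
            "glm_intercept": fit.intercept,
        }
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        _write_run_log(outdir, scenario, params, lex_report, tally_report, fit)

    return PipelineResult(
        scenario=scenario,
        params=params,
        truth=truth,
        counts=counts,
        estimates=est,
        ranks=ranks,
        diffs=diffs,
        rdg_counts=counts_by_year,
        groups=groups,
        intersections=inter,
        topk=topk,
        glm_fit=fit,
        classification=cls,
        outdir=outdir,
        summary=summary,
    )


def _write_outputs(
    outdir: Path, counts, est, ranks, diffs, counts_by_year, groups, inter, topk,
    fit, cls,
) -> None:
    counts.to_frame().to_csv(outdir / "counts.csv", index=False)
    est.to_frame(counts).to_csv(
        outdir / "estimates.csv", index=False, float_format=_FLOAT_FMT
    )
    ranks.to_frame().to_csv(outdir / "ranks.csv", index=False)
    diffs.to_frame().to_csv(outdir / "diffs.csv", index=False)
    counts_by_year.to_csv(outdir / "rdg_counts.csv")
    groups.table.to_csv(
        outdir / "group_summary.csv", index=False, float_format=_FLOAT_FMT
    )
    groups.pearson_r.to_csv(outdir / "pearson.csv", float_format=_FLOAT_FMT)
    inter.table.to_csv(outdir / "intersections.csv", index=False)
    topk.to_frame().to_csv(outdir / "topk.csv", index=False)
    fit.to_frame().to_csv(outdir / "glm.csv", index=False, float_format=_FLOAT_FMT)
    cls.to_frame().to_csv(outdir / "classification.csv", index=False)


def _write_run_log(outdir, scenario, params, lex_report, tally_report, fit) -> None:
    import numpy, pandas, scipy, statsmodels  # local: versions for the run log

    lines = [
        f"rarelens {__version__}",
        f"numpy {numpy.__version__}, pandas {pandas.__version__}, "
        f"scipy {scipy.__version__}, statsmodels {statsmodels.__version__}",
        f"seed: {scenario.seed}",
        f"scenario: {json.dumps(scenario.to_dict(), sort_keys=True)}",
        f"params: cutoff={params.cutoff} block_size={params.block_size} "
        f"top_k={params.top_k} baseline_year={params.baseline_year} "
        f"policy={params.classify_policy} match_mode={params.match_mode}",
        f"lexicon: {lex_report.n_active} active of {lex_report.n_total} "
        f"(dropped: {list(lex_report.dropped_ids)})",
        f"log lines per year: {tally_report.lines_per_year}",
        f"malformed lines: {tally_report.malformed_lines}; "
        f"out-of-range lines: {tally_report.out_of_range_lines}",
        f"glm: n_obs={fit.n_obs}, encoding={fit.encoding}",
    ]
    (Path(outdir) / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
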