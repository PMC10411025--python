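import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rarelens.config import ScenarioConfig, default_scenario
from rarelens.pipeline import run_pipeline
from rarelens.ranking import DiffTable, code_rdg

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A 15-disease two-year scenario small enough for exhaustive checks."""
    return ScenarioConfig(
        n_diseases=15,
        years=(2016, 2017),
        population={2016: 1.0e5, 2017: 1.1e5},
        prevalence_logmu=-8.0,
        prevalence_logsigma=1.0,
        search_rate=1.5,
        publicity_spike_prob=0.2,
        publicity_spike_scale=4.0,
        reporting_alpha=2.0,
        reporting_beta=3.0,
        background_queries={2016: 500, 2017: 400},
        seed=7,
    )


@pytest.fixture(scope="session")
def default_result(tmp_path_factory):
    """One full run of the shipped default scenario, shared across tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline(default_scenario(), outdir)


def make_difftable(rdg_rows, years, cutoff=20, diff_rows=None) -> DiffTable:
    """Build a DiffTable directly from per-disease RDG codes (test helper).

    When explicit diffs are not given, codes are mapped to representative
    differences (-cutoff-10, 0, +cutoff+10) consistent with the coding.
    """
    ids = [f"D{i:03d}" for i in range(1, len(rdg_rows) + 1)]
    rdg = pd.DataFrame(
        np.asarray(rdg_rows, dtype=np.int64),
        index=pd.Index(ids, name="disease_id"),
        columns=pd.Index(list(years), name="year"),
    )
    if diff_rows is None:
        diff = rdg.replace({0: -cutoff - 10, 1: 0, 2: cutoff + 10}).astype(np.int64)
    else:
        diff = pd.DataFrame(
            np.asarray(diff_rows, dtype=np.int64),
            index=rdg.index.copy(),
            columns=rdg.columns.copy(),
        )
        assert (code_rdg(diff.to_numpy(), cutoff) == rdg.to_numpy()).all()
    return DiffTable(diff=diff, rdg=rdg, cutoff=cutoff)
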