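import warnings

import numpy as np
import pandas as pd
import pytest

from hetefx import (
    CohortTable,
    PipelineConfig,
    VariableRoles,
    preset,
    run_pipeline,
    simulate_cohort,
    simulation_roles,
)


@pytest.fixture(autouse=True)
def _quiet_role_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="candidate modifiers not in the confounder set.*"
        )
        yield


@pytest.fixture
def toy_table() -> CohortTable:
    """Tiny deterministic cohort: one binary and one continuous covariate."""
    rng = np.random.default_rng(42)
    n = 40
    df = pd.DataFrame(
        {
            "treatment": np.r_[np.zeros(n // 2), np.ones(n // 2)],
            "y": rng.random(n).round(3),
            "c_bin": rng.integers(0, 2, n).astype(float),
            "c_cont": rng.normal(10, 2, n),
        }
    )
    return CohortTable(df)


@pytest.fixture
def toy_roles() -> VariableRoles:
    return VariableRoles(confounders=["c_bin", "c_cont"],
                         candidate_modifiers=["c_bin", "c_cont"])


def pipeline_config(seed: int) -> PipelineConfig:
    cfg = PipelineConfig(roles=simulation_roles())
    cfg.design.seed = seed
    cfg.penalty.fold_seed = seed
    cfg.jitter_seed = seed
    return cfg


@pytest.fixture(scope="session")
def a1_sim():
    return simulate_cohort(preset("a1", seed=0))


@pytest.fixture(scope="session")
def a1_result(a1_sim):
    """One full seven-step run on the a1 cohort, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(a1_sim.table, pipeline_config(0))
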