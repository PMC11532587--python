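import numpy as np
import pandas as pd
import pytest

from smokemr import SimulationConfig, simulate_minimal
from smokemr.simcohort import snp_panel


@pytest.fixture(scope="session")
def null_config():
    """Valid-instrument null: no causal effect, no confounding, no pleiotropy."""
    return SimulationConfig(
        n_individuals=10_000,
        gwas_n_individuals=10_000,
        causal_effect=0.0,
        confounder_effects=(0.0, 0.0),
        seed=101,
    )


@pytest.fixture(scope="session")
def causal_config():
    """Planted causal effect 0.3 log-odds per index unit, no confounding."""
    return SimulationConfig(
        n_individuals=10_000,
        gwas_n_individuals=10_000,
        causal_effect=0.3,
        confounder_effects=(0.0, 0.0),
        seed=202,
    )


@pytest.fixture(scope="session")
def confounded_null_config():
    """The reference scenario: observational association, causal null."""
    return SimulationConfig(n_individuals=10_000, causal_effect=0.0, seed=303)


def minimal_cohort_frame(config, seed):
    """Bare cohort frame (outcome + exposure only) from the lean generator."""
    d = simulate_minimal(config, seed)
    frame = pd.DataFrame({"ckd_event": d["y"], "smoking_index": d["x"]})
    return frame, d


@pytest.fixture(scope="session")
def harmonized_null(null_config):
    """Harmonized summary table under the valid-instrument null."""
    from smokemr import harmonize, simulate_summary_stats

    ex, out = simulate_summary_stats(null_config, 11, 22)
    return harmonize(ex, out)


@pytest.fixture()
def toy_summary():
    """Tiny hand-written harmonized table for arithmetic checks."""
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(5)],
            "beta_exp": [0.10, 0.12, 0.08, 0.15, 0.11],
            "se_exp": [0.01, 0.012, 0.009, 0.02, 0.011],
            "beta_out": [0.030, 0.041, 0.020, 0.050, 0.031],
            "se_out": [0.015, 0.02, 0.012, 0.025, 0.018],
            "eaf": [0.2, 0.3, 0.4, 0.25, 0.35],
            "palindromic": [False] * 5,
        }
    )
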