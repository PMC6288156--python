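import numpy as np
import pandas as pd
import pytest

from seedtrace import synthetic_data as sd


@pytest.fixture(scope="session")
def small_discovery():
    """A scaled-down discovery cohort (fewer genes, full 57-sample design)."""
    cfg = sd.SimulationConfig(n_genes=800, n_clone_genes=100, seed=11)
    expr, annotation, truth = sd.gen_multifocal_counts(cfg)
    return cfg, expr, annotation, truth


@pytest.fixture(scope="session")
def survival_cohort():
    """A survival cohort with a planted 3-gene prognostic signal."""
    panel = ["GA", "GB", "GC"]
    beta = {"GA": 0.6, "GB": -0.5, "GC": 0.4}
    expr, clinical, truth = sd.gen_survival_cohort(
        n_patients=300, panel=panel, beta=beta, censoring_rate=0.4, seed=7
    )
    return panel, beta, expr, clinical, truth


@pytest.fixture
def toy_clinical():
    """Eight patients, distinct event/censor times, one continuous covariate."""
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(8)],
            "time": [2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0],
            "event": [True, True, False, True, True, False, True, True],
            "x": [1.2, -0.4, 0.3, 0.9, -1.1, 0.0, -0.7, 0.5],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
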