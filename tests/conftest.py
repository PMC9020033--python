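import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from epigreml import (
    SimulationTruth,
    compute_similarity,
    simulate_cohort,
    standardize,
    winsorize_matrix,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with real methylation signal, shared across tests."""
    truth = SimulationTruth(
        h2_m=0.5, var_batch=0.05, var_covariates=0.1, seed=11
    )
    return simulate_cohort(150, 300, truth)


@pytest.fixture(scope="session")
def small_similarity(small_cohort):
    Z = standardize(winsorize_matrix(small_cohort.betas))
    return compute_similarity(Z)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def standardized_matrix(rng, n, p):
    """Helper: a column-standardized matrix wrapped at the 'standardized' stage."""
    from epigreml import MethylationMatrix

    x = rng.standard_normal((n, p))
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    return MethylationMatrix(
        values=z,
        sample_ids=[f"s{i}" for i in range(n)],
        probe_ids=[f"cg{j}" for j in range(p)],
        stage="standardized",
    )
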