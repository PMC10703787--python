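import numpy as np
import pandas as pd
import pytest

from mksers import CohortConfig, simulate_cohort
from mksers.matrix import ExpressionMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def small_matrix(rng):
    """12 features x 20 samples, generic platform, no missing values."""
    vals = rng.normal(7.0, 1.0, size=(12, 20))
    features = [f"G{i:02d}" for i in range(12)]
    samples = [f"S{i:02d}" for i in range(20)]
    return ExpressionMatrix(pd.DataFrame(vals, index=features, columns=samples))


@pytest.fixture(scope="session")
def default_cohort():
    """One large cohort at the default study conditions, shared across tests."""
    return simulate_cohort(CohortConfig(n_samples=2000, seed=42))
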