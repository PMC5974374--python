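import numpy as np
import pandas as pd
import pytest

from e2fsig import SimConfig, average_duplicates, simulate_cohort
from e2fsig.io import ExpressionMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-design cohort: 55 patients, 12 high, effect 1.5."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def averaged_matrix(default_cohort):
    return average_duplicates(default_cohort.expression, default_cohort.pairing)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for structural tests: 20 patients, 120 genes."""
    return simulate_cohort(
        SimConfig(seed=4, n_patients=20, n_genes=120, n_up_markers=11, n_down_markers=13)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_matrix(rng, n_genes=6, n_samples=4, scale="linear", prefix="G"):
    vals = rng.uniform(1.0, 100.0, size=(n_genes, n_samples))
    df = pd.DataFrame(
        vals,
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df, scale=scale)
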