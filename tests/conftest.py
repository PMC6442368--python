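import numpy as np
import pandas as pd
import pytest

from granudx import CohortConfig, generate_cohort, log2_transform


@pytest.fixture(scope="session")
def small_cohort():
    """800-protein, 30-healthy cohort with the default patient roster."""
    return generate_cohort(CohortConfig(n_proteins=800, n_healthy=30, seed=11))


@pytest.fixture(scope="session")
def small_log2(small_cohort):
    return log2_transform(small_cohort.matrix)


@pytest.fixture()
def toy_matrix_df():
    return pd.DataFrame(
        [[8.0, 4.0], [2.0, 1.0]],
        index=["P1", "P2"],
        columns=["S1", "S2"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
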