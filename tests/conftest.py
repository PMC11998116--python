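import numpy as np
import pytest

import big3sim as b3


@pytest.fixture(scope="session")
def params():
    return b3.default_parameters()


@pytest.fixture(scope="session")
def small_cohort(params):
    """2,000-individual synthetic cohort shared across read-only tests."""
    return b3.generate_cohort(b3.CohortConfig(n_individuals=2000, seed=123), params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def three_sd_binomial(p, n):
    """Half-width of a 3-SD binomial band for a frequency estimate."""
    return 3 * np.sqrt(p * (1 - p) / n)
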