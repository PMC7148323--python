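import numpy as np
import pytest

from twasim import DGPParams, builtin_cohort_table, simulate_population


@pytest.fixture(scope="session")
def cohort_table():
    return builtin_cohort_table()


@pytest.fixture(scope="session")
def gtex_women(cohort_table):
    return cohort_table[("GTEx", "women")]


@pytest.fixture(scope="session")
def nhanes_women(cohort_table):
    return cohort_table[("NHANES", "women")]


@pytest.fixture(scope="session")
def default_population():
    """One full-size population under the default generative constants."""
    return simulate_population(DGPParams(), seed=20260923)


@pytest.fixture(scope="session")
def small_population():
    """A reduced population for sampling-level tests."""
    return simulate_population(DGPParams(pop_size=20_000), seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
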