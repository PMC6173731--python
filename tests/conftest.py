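import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from clonotrace.synthetic import (
    CountsSimConfig,
    GradientConfig,
    simulate_counts,
    simulate_indexsort,
)


@pytest.fixture(scope="session")
def default_sim():
    """One default-size index-sort simulation shared across tests."""
    return simulate_indexsort(GradientConfig(n_cells=2000, seed=11))


@pytest.fixture(scope="session")
def counts_sim():
    return simulate_counts(CountsSimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def hill(t, ec50, h, plateau):
    return plateau / (1.0 + (ec50 / np.asarray(t, dtype=float)) ** h)


@pytest.fixture(scope="session")
def noiseless_curve():
    t = np.arange(12.0, 97.0, 12.0)
    return pd.DataFrame({"t": t, "fraction": hill(t, 60.0, 4.0, 0.9)})
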