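import numpy as np
import pytest

from darpipe.features import featurize_days
from darpipe.simulate import SyntheticConfig, simulate_population


@pytest.fixture(scope="session")
def tiny_pop():
    """A small labelled population shared by unit tests (read-only)."""
    return simulate_population(
        SyntheticConfig(n_animals=15, days_per_animal=20, seed=5))


@pytest.fixture(scope="session")
def tiny_features(tiny_pop):
    return featurize_days(tiny_pop.labeled_days, tiny_pop.grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
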