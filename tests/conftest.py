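import warnings

import numpy as np
import pytest

from trendsieve.cohort import label_cohort
from trendsieve.synthetic import SyntheticConfig, fixture_small, generate


@pytest.fixture()
def fixture_cohort():
    """The deterministic 12-patient micro-cohort, labeled."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return label_cohort(fixture_small())


@pytest.fixture(scope="session")
def small_cohort():
    """A labeled 80-patient synthetic cohort shared across tests."""
    return label_cohort(generate(SyntheticConfig(n_patients=80, seed=42)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
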