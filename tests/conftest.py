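import numpy as np
import pytest

from cateselect import (
    SimulationConfig,
    build_caussim_family,
    fit_candidate,
    sample_dataset,
)
from cateselect.selection import split_data


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the simulator defaults, reused across read-only tests."""
    return sample_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_family():
    """A 24-member ridge family (2 featurization seeds), cheap to fit."""
    return build_caussim_family(n_bases=2, seed=0)


@pytest.fixture(scope="session")
def fitted_small_family(default_dataset, small_family):
    """Candidates of the small family fitted on a 90% training split."""
    train_idx, test_idx = split_data(default_dataset, 0.9, seed=0)
    train = default_dataset.subset(train_idx)
    fitted = [fit_candidate(s, train, train_idx) for s in small_family]
    return fitted, train_idx, test_idx


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
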