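import warnings

import numpy as np
import pytest

from tvasem.synthetic import SyntheticCohortConfig


@pytest.fixture
def small_config():
    """Compact cohort: quick to simulate and fit, same structure as the default."""
    return SyntheticCohortConfig(
        n_participants=24,
        trials_per_exposure=20,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Silence the advisory few-trials/laterality warnings in bulk simulations."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*trials.*")
        warnings.filterwarnings("ignore", message=".*exposure durations.*")
        yield
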