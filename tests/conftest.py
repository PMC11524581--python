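import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqdyn import SyntheticSpec, default_true_params, generate_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """20 synthetic proteins (80-150 residues) generated without noise."""
    return generate_dataset(SyntheticSpec(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset():
    """20 synthetic proteins with the default 0.3 s^-1 measurement noise."""
    return generate_dataset(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """A cheaper dataset for tests that train repeatedly."""
    return generate_dataset(
        SyntheticSpec(n_proteins=10, length_range=(40, 70), noise_sd=0.2, seed=13)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
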