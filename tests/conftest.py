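import warnings

import pytest

from iatdyn.synthetic_data import SyntheticConfig, simulate_iat


def pytest_configure(config):
    # optimizer exploration can transiently hit extreme parameter regions
    warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_sim():
    """Ten synthetic participants with the default study conditions."""
    cfg = SyntheticConfig(n_participants=10, seed=11)
    return simulate_iat(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim[1]
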