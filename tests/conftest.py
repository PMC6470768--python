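import numpy as np
import pytest

from milkomics.synthetic import SyntheticConfig, generate_blocks, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def default_blocks(default_config, default_cohort):
    return generate_blocks(default_cohort, default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_group_data(rng, n_per_group=20, p=10, effect=0.0, n_signal=0):
    """Two-class Gaussian fixture; first ``n_signal`` features shifted
    by ``effect`` standard deviations between groups."""
    X = rng.standard_normal((2 * n_per_group, p))
    labels = np.array(["a"] * n_per_group + ["b"] * n_per_group, dtype=object)
    if n_signal:
        X[labels == "b", :n_signal] += effect
    return X, labels
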