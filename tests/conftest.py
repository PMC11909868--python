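import numpy as np
import pytest

from ipfcea import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def base_params(registry):
    return registry.realize("base")


@pytest.fixture(scope="session")
def mean_params(registry):
    return registry.realize("distribution_mean")


@pytest.fixture(scope="session")
def random_parameter_sets(registry):
    """A bank of independent PSA draws used by property tests."""
    return [
        registry.realize("sample", rng=np.random.default_rng(10_000 + i))
        for i in range(50)
    ]
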