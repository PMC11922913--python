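import numpy as np
import pytest

from mammofusion import phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_dataset():
    """Default-configuration phantom set shared across tests (100 per class)."""
    return phantoms.generate_dataset(phantoms.PhantomConfig())


@pytest.fixture(scope="session")
def small_phantom_dataset():
    """A small, quick phantom set for I/O and CLI tests."""
    cfg = phantoms.PhantomConfig(image_size=64, n_benign=8, n_malignant=8, seed=3)
    return phantoms.generate_dataset(cfg)
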