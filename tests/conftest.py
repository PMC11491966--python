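import numpy as np
import pytest

from gwbcoseg.phantom import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Twelve 32×32 phantom cases shared by I/O and pipeline tests."""
    return generate_dataset(12, PhantomConfig(image_size=32), seed=99)
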