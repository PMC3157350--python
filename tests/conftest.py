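import numpy as np
import pytest

from facetraits import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """24 synthetic faces with default planted trait models (fixed seed)."""
    samples, manifest = generate_dataset(SyntheticConfig(n_faces=24, seed=11))
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
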