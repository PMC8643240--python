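import numpy as np
import pytest

from prostseg import phantoms, pssnet


@pytest.fixture(scope="session")
def default_params():
    return phantoms.PhantomParams()


@pytest.fixture(scope="session")
def small_dataset(default_params):
    """32 seeded phantoms at the default 64x64 size."""
    return [phantoms.generate_phantom(default_params, 1000 + i) for i in range(32)]


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """A model trained well enough to segment phantoms cleanly (shared)."""
    config = pssnet.NetworkConfig(epochs=25, seed=7)
    model, log = pssnet.train_pssnet(small_dataset, config)
    return model, log
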