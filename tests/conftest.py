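import numpy as np
import pytest

from fedpartseg.phantoms import PhantomConfig, make_federated_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """Small phantom geometry used by unit tests (fast to generate)."""
    return PhantomConfig(image_size=(32, 32), n_samples_per_client=4, seed=7)


@pytest.fixture(scope="session")
def small_datasets(small_cfg):
    return make_federated_dataset(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
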