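import numpy as np
import pytest

from tganet import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def coating_items():
    """Small coating-task dataset shared across tests (5 per class, 64x64)."""
    spec = SyntheticSpec(image_size=(64, 64), n_per_class=5, task="coating", seed=101)
    items, table = generate_dataset(spec)
    return items, table


@pytest.fixture(scope="session")
def color_items():
    spec = SyntheticSpec(image_size=(64, 64), n_per_class=8, task="color", seed=102)
    items, table = generate_dataset(spec)
    return items, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
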