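import numpy as np
import pytest

from advpercept.synthetic_data import (
    SyntheticDatasetSpec,
    Testbed,
    generate_dataset,
    make_default_testbed,
)


@pytest.fixture(scope="session")
def testbed() -> Testbed:
    """The frozen default testbed (trained once per test session)."""
    return make_default_testbed(seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SyntheticDatasetSpec(images_per_class=10, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
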