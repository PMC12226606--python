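import numpy as np
import pytest

from sgdiff.scenes import GeneratorConfig, default_class_table, sample_scenes


@pytest.fixture(scope="session")
def class_table():
    return default_class_table()


@pytest.fixture(scope="session")
def small_scenes():
    """A small bank of 32x32 scenes shared across tests."""
    return sample_scenes(64, GeneratorConfig(canvas=32), seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
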