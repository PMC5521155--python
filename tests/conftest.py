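import numpy as np
import pytest

from gatetest import EffectConfig, TraitMatrix, simulate_dataset, structure_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """One S3 dataset at moderate size, shared by read-only tests."""
    spec = structure_spec("S3")
    effect = EffectConfig(maf=0.3, n=600)
    return simulate_dataset(spec, effect, seed=42)


@pytest.fixture
def random_traits(rng):
    return TraitMatrix(rng.standard_normal((200, 6)))
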