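import numpy as np
import pytest

from dafh.data_pipeline import stratified_split
from dafh.network import DAFHNet
from dafh.synthetic import SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def four_class_corpus():
    """200 noiseless synthetic images, 4 classes x 50, side 64."""
    spec = SyntheticSpec(n_classes=4, per_class_counts=[50] * 4,
                         image_side=64, noise_sd=0.0, seed=1)
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def small_corpus():
    """Fast corpus for structural tests: 2 classes x 10, side 32."""
    spec = SyntheticSpec(n_classes=2, per_class_counts=[10, 10],
                         image_side=32, noise_sd=0.05, seed=3)
    return generate_synthetic(spec)


@pytest.fixture
def small_split(small_corpus):
    return stratified_split(list(small_corpus), ratio=0.8, seed=3)


@pytest.fixture
def tiny_net():
    return DAFHNet(hash_length=16, n_classes=2, image_side=32, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
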