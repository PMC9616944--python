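import numpy as np
import pytest

from dermclf import LabelCodec, SynthConfig, load_images
from dermclf.synthgen import generate_dataset


@pytest.fixture(scope="session")
def codec():
    return LabelCodec()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """2 images/class at 32px: enough for plumbing and determinism tests."""
    root = tmp_path_factory.mktemp("tiny")
    manifest = generate_dataset(SynthConfig(n_per_class=2, image_size=32, seed=11), root)
    return root, manifest


@pytest.fixture(scope="session")
def learnable_dataset(tmp_path_factory):
    """50 images/class at 64px: separable enough for every classifier."""
    root = tmp_path_factory.mktemp("learnable")
    manifest = generate_dataset(SynthConfig(n_per_class=50, image_size=64, seed=7), root)
    return root, manifest


@pytest.fixture(scope="session")
def learnable_images(learnable_dataset):
    _, manifest = learnable_dataset
    return load_images(manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
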