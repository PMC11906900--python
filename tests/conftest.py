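import numpy as np
import pytest

from dbahnet import (PhantomParams, PreprocessConfig, generate_phantom,
                     preprocess_pipeline)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with ground-truth labels (session-cached)."""
    params = PhantomParams(seed=7, noise_sigma=0.0)
    vol, labels = generate_phantom(params)
    return params, vol, labels


@pytest.fixture(scope="session")
def noisy_phantom():
    params = PhantomParams(seed=8)
    vol, labels = generate_phantom(params)
    return params, vol, labels


@pytest.fixture(scope="session")
def preprocessed_crop(noisy_phantom):
    """A z-scored (64, 64, 32) crop of a preprocessed phantom, with labels."""
    _, vol, labels = noisy_phantom
    cvol, _, clab = preprocess_pipeline(vol, PreprocessConfig(), labels)
    shape = cvol.shape
    sl = tuple(slice((s - c) // 2, (s - c) // 2 + c)
               for s, c in zip(shape, (64, 64, 32)))
    return cvol.voxels[sl].copy(), clab.voxels[sl].copy()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
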