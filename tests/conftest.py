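import numpy as np
import pytest
from hypothesis import settings

from mammoprep import PhantomSpec, generate_phantom

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free default phantom with ground truth."""
    return generate_phantom(PhantomSpec(seed=11, noise_sigma=0.0))


@pytest.fixture(scope="session")
def phantom_default():
    """Default (mildly noisy) phantom."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()
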