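import numpy as np
import pytest

from metabrand.branding import build_marker_set
from metabrand.cohort import BinnedMetadata
from metabrand.synthetic import PhantomParams, simulate_volume


@pytest.fixture(scope="session")
def markers():
    return build_marker_set(42)


@pytest.fixture(scope="session")
def meta():
    return BinnedMetadata("66-75", "Female", "11-13", "Married", "Negative")


@pytest.fixture(scope="session")
def phantom_volume():
    """One deterministic phantom scan, shared across tests."""
    return simulate_volume("Control", PhantomParams(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_slice(rng):
    """A noisy 8-bit test slice with brain-like structure."""
    img = np.zeros((224, 224), dtype=np.float64)
    yy, xx = np.mgrid[0:224, 0:224]
    img[((yy - 112) / 90) ** 2 + ((xx - 112) / 80) ** 2 <= 1.0] = 180.0
    img += rng.normal(0, 10, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
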