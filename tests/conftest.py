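import numpy as np
import pytest

from flairjoint.radiomics import FeatureCatalog, LesionImage


@pytest.fixture(scope="session")
def catalog():
    return FeatureCatalog()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ball_lesion(radius_vox=5, spacing=(1.0, 1.0, 1.0), intensity=None, seed=0):
    """A digital ball lesion with (optionally random) intensities."""
    n = 2 * radius_vox + 3
    x, y, z = np.indices((n, n, n))
    c = n // 2
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2
    if intensity is None:
        intensity = np.random.default_rng(seed).normal(100.0, 10.0, (n, n, n))
    else:
        intensity = np.full((n, n, n), float(intensity))
    return LesionImage(intensity, mask, spacing, "ball", "test")


@pytest.fixture
def ball_lesion():
    return make_ball_lesion()
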