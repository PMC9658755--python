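import numpy as np
import pytest

from facescatter import LandmarkSet, PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cloud(rng):
    return PointCloud(rng.normal(scale=10.0, size=(300, 3)), sample_id="small")


@pytest.fixture
def landmarks22(rng):
    return LandmarkSet(rng.normal(scale=50.0, size=(22, 3)))


def random_landmarks(rng, C, scale=50.0):
    return LandmarkSet(rng.normal(scale=scale, size=(C, 3)))
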