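import numpy as np
import pytest

from clgflow3d import SceneSpec, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_volume(rng):
    return VolumeImage(rng.uniform(0.0, 1.0, size=(5, 6, 7)), spacing=1.0)


@pytest.fixture
def ramp_volume():
    """I(x,y,z) = 2x + 3y - z + 5: trilinear, so interpolation is exact."""
    x, y, z = np.meshgrid(np.arange(8.0), np.arange(8.0), np.arange(8.0), indexing="ij")
    return VolumeImage(2 * x + 3 * y - z + 5)


@pytest.fixture
def blob_scene():
    return SceneSpec(
        dims=(16, 16, 16),
        blobs=(((8.0, 8.0, 8.0), 3.0, 100.0), ((4.0, 11.0, 5.0), 2.5, 80.0)),
        background=10.0,
    )
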