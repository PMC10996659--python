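import numpy as np
import pytest

from epiqc.data_io import VolumeSeries
from epiqc.synthgen import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture
def small_vol(rng):
    """A 8x8x6x40 noise series with an ellipsoidal mask, single run."""
    data = 100.0 + rng.normal(0, 1.0, size=(8, 8, 6, 40))
    vol = VolumeSeries(data, voxdims=(3.0, 3.0, 3.0), tr=2.0)
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, 8), np.linspace(-1, 1, 8), np.linspace(-1, 1, 6),
        indexing="ij",
    )
    mask = (x**2 + y**2 + z**2) < 0.9
    return vol, mask


@pytest.fixture
def quiet_phantom():
    """Default phantom with no artifacts, shortened for test speed."""
    return make_phantom(PhantomSpec(seed=11, run_lengths=[80]))
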