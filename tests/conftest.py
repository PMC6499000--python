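import numpy as np
import pytest

from spheroquant.phantoms import SpheroidPhantomSpec, make_spheroid_images


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disk_phantom():
    """Noiseless 200 um disk, no halo: the simplest segmentation oracle."""
    spec = SpheroidPhantomSpec(core_radius_um=200.0, halo_cell_count=0,
                               noise_sd=0.0, seed=7)
    image, truth = make_spheroid_images(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def halo_phantom():
    """Noisy spheroid with 200 loose halo cells around a 200 um core."""
    spec = SpheroidPhantomSpec(core_radius_um=200.0, halo_cell_count=200,
                               noise_sd=2.0, seed=11)
    image, truth = make_spheroid_images(spec)
    return spec, image, truth
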