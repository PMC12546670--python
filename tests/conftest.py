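import numpy as np
import pytest

from msifusion.simulate import (CubeSimConfig, ImageSimConfig,
                                SpectralSimConfig, generate_hypercube)


@pytest.fixture(scope="session")
def small_spectral_cfg():
    """12 classes, few samples, reduced band count for fast tests."""
    return SpectralSimConfig(n_classes=12, n_per_class=5, n_bands=128, seed=7)


@pytest.fixture(scope="session")
def image_cfg():
    return ImageSimConfig(n_classes=3, canvas_size=64, seed=3)


@pytest.fixture(scope="session")
def cube_sim(small_spectral_cfg):
    """Default 5x5 hypercube with three sub-threshold specks."""
    cfg = CubeSimConfig(speck_count=3, speck_area_px=20, seed=1)
    classes = np.arange(25) % 12
    return generate_hypercube(cfg, classes, small_spectral_cfg)


@pytest.fixture(scope="session")
def corrected_cube(cube_sim):
    from msifusion.hsi import black_white_correct

    return black_white_correct(cube_sim.raw, cube_sim.white, cube_sim.dark,
                               grid=cube_sim.grid)
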