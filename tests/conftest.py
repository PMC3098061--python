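import logging

import numpy as np
import pytest

from spotbench.core_image import GrayImage
from spotbench.simulate import SimConfig, generate_scene

logging.getLogger("spotbench").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(12345))


@pytest.fixture
def flat_image():
    return GrayImage(np.full((32, 32), 50.0))


@pytest.fixture
def spot_image():
    """One Gaussian spot (sigma 2) on a flat background of 10."""
    rr, cc = np.mgrid[0:41, 0:41]
    spot = 100.0 * np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / (2 * 2.0**2))
    return GrayImage(10.0 + spot)


@pytest.fixture(scope="session")
def standard_scene():
    return generate_scene(SimConfig(seed=7))


def gaussian_spot(shape, center, sigma, amplitude, background=0.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return background + amplitude * np.exp(-d2 / (2.0 * sigma**2))
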