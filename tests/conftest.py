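import numpy as np
import pytest

from metaspi import optics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def library():
    return optics.NanobrickLibrary.bundled()


def brightfield_scene(image: np.ndarray, c2: float = 0.5) -> np.ndarray:
    """Reference bright-field output |E_M|^2 for a given scene."""
    n = image.shape[0]
    h = optics.constant_transfer(n, c2)
    return optics.field_intensity(optics.apply_4f(optics.ComplexField(image), h))


def edge_scene(image: np.ndarray, c1: float = 0.0) -> np.ndarray:
    """Reference edge-enhanced output |E_M|^2 for a given scene."""
    n = image.shape[0]
    h = optics.spiral_transfer(n, c1)
    return optics.field_intensity(optics.apply_4f(optics.ComplexField(image), h))
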