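import warnings

import numpy as np
import pytest

from mitonetquant import BinaryMask, GrayImage

warnings.filterwarnings("ignore", category=FutureWarning)


def mask(px: np.ndarray, pixel_size_um: float = 1.0) -> BinaryMask:
    return BinaryMask(np.asarray(px, dtype=bool), pixel_size_um)


@pytest.fixture
def plus_cross() -> np.ndarray:
    """Two 21-px perpendicular 1-px lines sharing their centre pixel."""
    m = np.zeros((21, 21), dtype=bool)
    m[10, :] = True
    m[:, 10] = True
    return m


@pytest.fixture
def h_shape() -> np.ndarray:
    """Two 21-px vertical lines joined at their 11th pixel by a 9-px rung."""
    m = np.zeros((21, 21), dtype=bool)
    m[:, 5] = True
    m[:, 15] = True
    m[10, 6:15] = True
    return m


@pytest.fixture
def diagonal_11() -> np.ndarray:
    """An 11-px perfect diagonal segment."""
    m = np.zeros((15, 15), dtype=bool)
    for i in range(11):
        m[2 + i, 2 + i] = True
    return m


@pytest.fixture
def annulus() -> np.ndarray:
    """A filled ring (disk of radius 8 minus disk of radius 4)."""
    from skimage.morphology import disk

    outer = np.zeros((25, 25), dtype=bool)
    outer[4:21, 4:21] = disk(8).astype(bool)
    inner = np.zeros((25, 25), dtype=bool)
    inner[8:17, 8:17] = disk(4).astype(bool)
    return outer & ~inner


def gray(px: np.ndarray, pixel_size_um: float = 1.0, bit_depth: int = 8) -> GrayImage:
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return GrayImage(np.asarray(px, dtype=dtype), pixel_size_um=pixel_size_um, source_id="test")
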