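import numpy as np
import pytest

from contractile_escape import PIVSettings
from contractile_escape.synthetic import make_speckle_frame


@pytest.fixture(scope="session")
def speckle_frame() -> np.ndarray:
    """Reference speckle texture shared across PIV tests."""
    return make_speckle_frame((256, 256), density=0.08, seed=1).astype(float)


@pytest.fixture(scope="session")
def piv_settings() -> PIVSettings:
    return PIVSettings()


def warp_frame(frame: np.ndarray, shift_x: float, shift_y: float = 0.0) -> np.ndarray:
    """Backward-warp a frame by a uniform shift (bilinear, 8-bit quantized)."""
    from scipy import ndimage

    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    out = ndimage.map_coordinates(frame, [yy - shift_y, xx - shift_x], order=1, mode="constant")
    return np.clip(np.round(out), 0, 255)


def interior(valid: np.ndarray, pad: int = 1) -> np.ndarray:
    """Mask selecting interior grid points (away from the inflow border)."""
    m = np.zeros_like(valid, dtype=bool)
    m[pad:-pad, pad:-pad] = True
    return m
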