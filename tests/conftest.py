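import numpy as np
import pytest

from gliamorph.core import PixelCalibration


@pytest.fixture
def cal_half() -> PixelCalibration:
    return PixelCalibration(0.5)


def random_pixel_mask(rng: np.random.Generator, n_pixels: int = 30,
                      side: int = 24) -> np.ndarray:
    """A random sparse pixel set (not necessarily connected)."""
    mask = np.zeros((side, side), dtype=bool)
    idx = rng.choice(side * side, size=n_pixels, replace=False)
    mask.flat[idx] = True
    return mask


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
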