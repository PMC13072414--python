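"""Small image helpers shared across the package.

Images travel through the package as float arrays in [0, 1] with shape
(H, W, 3); datasets store uint8.  Resizing goes through Pillow (bilinear),
blurring through scipy.ndimage.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image
from scipy import ndimage


def to_float(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return np.asarray(img, dtype=np.float64)


def to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def resize(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a float [0,1] image to (height, width)."""
    h, w = size
    pil = Image.fromarray(to_uint8(img))
    return to_float(np.asarray(pil.resize((w, h), Image.BILINEAR)))


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Channel-wise Gaussian blur of a float image."""
    if sigma <= 0:
        return img
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[:, :, c] = ndimage.gaussian_filter(img[:, :, c], sigma=sigma, mode="nearest")
    return out


__all__ = ["to_float", "to_uint8", "resize", "gaussian_blur", "rgb_to_hsv", "hsv_to_rgb"]
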