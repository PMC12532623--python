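"""Small shared image-derivative helpers.

All feature code works on float images in [0, 1] with the origin at the
top-left corner, x increasing rightward (columns) and y downward (rows).
Boundary handling is Neumann (mirror reflection, matching a
zero-flux diffusion boundary) throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# Scharr 3x3 first-derivative kernels, normalized so that a unit ramp
# (I = x) yields a derivative of exactly 1 per pixel.
SCHARR_X = np.array([[-3, 0, 3], [-10, 0, 10], [-3, 0, 3]], dtype=float) / 32.0
SCHARR_Y = SCHARR_X.T.copy()


def gaussian(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.asarray(img, dtype=float).copy()
    return ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma, mode="reflect")


def scharr_x(img: np.ndarray) -> np.ndarray:
    return ndimage.correlate(np.asarray(img, dtype=float), SCHARR_X, mode="reflect")


def scharr_y(img: np.ndarray) -> np.ndarray:
    return ndimage.correlate(np.asarray(img, dtype=float), SCHARR_Y, mode="reflect")


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = scharr_x(img)
    gy = scharr_y(img)
    return np.hypot(gx, gy)
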