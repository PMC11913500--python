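"""Color-space conversions: RGB <-> grayscale and RGB <-> CIELAB.

Grayscale uses the Rec. 601 luma weights (0.299, 0.587, 0.114), the
``RGB2GRAY`` convention of mainstream image libraries.  CIELAB assumes the
sRGB transfer curve and the D65 reference white — the dominant convention
for consumer-camera dermoscopy JPEGs — and is delegated to scikit-image.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

__all__ = ["to_grayscale", "rgb_to_lab", "lab_to_rgb"]

_REC601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma: ``0.299 R + 0.587 G + 0.114 B``, rounded to integers.

    Returns uint8 for uint8 input, float64 (of integer values) otherwise.
    When R = G = B the output equals the channel value exactly.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    gray = np.rint(arr.astype(np.float64) @ _REC601)
    if arr.dtype == np.uint8:
        return np.clip(gray, 0, 255).astype(np.uint8)
    return gray


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image in [0, 255] to CIELAB (float64 H x W x 3).

    L lies in [0, 100]; a and b are unbounded chromatic components,
    typically within [-128, 127] for in-gamut colors.
    """
    arr = np.asarray(image, dtype=np.float64) / 255.0
    return _skcolor.rgb2lab(arr)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`; out-of-gamut values clipped to [0, 255].

    Returns a uint8 RGB image.
    """
    rgb = _skcolor.lab2rgb(np.asarray(lab, dtype=np.float64))
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
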