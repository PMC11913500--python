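"""Smoothing and mathematical-morphology operators for hair detection.

The dehairing recipe is: Gaussian blur, median blur, grayscale conversion,
blackhat with an 11 x 11 cross-shaped structuring element, then binary
thresholding of the blackhat response.  The blackhat transform (closing
minus input) lights up dark structures thinner than the structuring
element — exactly the geometry of hair strands on brighter skin.

Border handling is reflect padding throughout (scipy's ``reflect`` mode,
which repeats the edge sample: ``d c b a | a b c d``).  With that
convention a normalised blur kernel preserves the image mean exactly.
Operators preserve dtype: uint8 in, uint8 out (rounded); float in, float
out.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "default_gaussian_sigma",
    "gaussian_blur",
    "median_blur",
    "make_cross_element",
    "dilate",
    "erode",
    "morphological_close",
    "blackhat",
    "threshold_binary",
]


def _check_odd(k: int, name: str) -> None:
    if k < 1 or k % 2 == 0:
        raise ValueError(f"{name} must be an odd positive integer, got {k}")


def _restore_dtype(out: np.ndarray, like: np.ndarray) -> np.ndarray:
    if like.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def default_gaussian_sigma(kernel_size: int) -> float:
    """Derive sigma from the kernel size: ``0.3*((k-1)*0.5 - 1) + 0.8``.

    This is the derive-from-kernel-size convention of the library family
    whose blur the dehairing recipe mirrors; k = 3 gives sigma = 0.8.
    """
    return 0.3 * ((kernel_size - 1) * 0.5 - 1) + 0.8


def gaussian_blur(
    image: np.ndarray, kernel_size: int = 3, sigma: float | None = None
) -> np.ndarray:
    """Convolve with a normalised, truncated discrete Gaussian kernel.

    Separable per-channel convolution with reflect padding; the kernel is
    sampled on ``kernel_size`` taps and normalised to sum to 1, so constant
    images (and the global mean) are preserved.
    """
    _check_odd(kernel_size, "kernel_size")
    if sigma is None:
        sigma = default_gaussian_sigma(kernel_size)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    arr = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return _restore_dtype(arr, np.asarray(image))
    radius = (kernel_size - 1) // 2
    if arr.ndim == 2:
        out = ndi.gaussian_filter(arr, sigma, mode="reflect", radius=radius)
    else:
        out = np.empty_like(arr)
        for ch in range(arr.shape[2]):
            out[:, :, ch] = ndi.gaussian_filter(
                arr[:, :, ch], sigma, mode="reflect", radius=radius
            )
    return _restore_dtype(out, np.asarray(image))


def median_blur(image: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Replace each pixel (per channel) by the median of its k x k window."""
    _check_odd(kernel_size, "kernel_size")
    arr = np.asarray(image)
    size = (
        (kernel_size, kernel_size)
        if arr.ndim == 2
        else (kernel_size, kernel_size, 1)
    )
    return ndi.median_filter(arr, size=size, mode="reflect")


def make_cross_element(size: int = 11) -> np.ndarray:
    """Cross-shaped (plus-sign) boolean structuring element of odd *size*.

    True exactly on the centre row and centre column: ``2*size - 1`` cells.
    """
    _check_odd(size, "size")
    se = np.zeros((size, size), dtype=bool)
    c = size // 2
    se[c, :] = True
    se[:, c] = True
    return se


def _check_se(se: np.ndarray) -> np.ndarray:
    se = np.asarray(se, dtype=bool)
    if se.ndim != 2 or se.shape[0] != se.shape[1] or se.shape[0] % 2 == 0:
        raise ValueError("structuring element must be square with odd size")
    if not se[se.shape[0] // 2, se.shape[1] // 2]:
        raise ValueError("structuring element anchor (centre) must be true")
    return se


def dilate(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Grayscale dilation: max over the structuring element's true offsets."""
    se = _check_se(se)
    arr = np.asarray(image)
    return ndi.grey_dilation(arr, footprint=se, mode="reflect")


def erode(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Grayscale erosion: min over the structuring element's true offsets."""
    se = _check_se(se)
    arr = np.asarray(image)
    return ndi.grey_erosion(arr, footprint=se, mode="reflect")


def morphological_close(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Closing = erosion of the dilation; fills dark gaps smaller than *se*."""
    return erode(dilate(image, se), se)


def blackhat(image: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Blackhat transform: ``close(image, se) - image`` (non-negative).

    Dark objects thinner than the structuring element come out as bright
    responses; everything else is near zero.
    """
    arr = np.asarray(image)
    closed = morphological_close(arr, se)
    # subtract in a signed dtype; closing is extensive so result is >= 0
    out = closed.astype(np.float64) - arr.astype(np.float64)
    return _restore_dtype(out, arr)


def threshold_binary(
    image: np.ndarray, thresh: float = 10.0, maxval: float = 255.0
) -> np.ndarray:
    """Boolean mask where ``image > thresh`` (strict; ties excluded).

    *maxval* only parameterises u8 mask export (`mask * maxval`) and must
    exceed *thresh*.
    """
    if not 0 <= thresh < maxval <= 255:
        raise ValueError("require 0 <= thresh < maxval <= 255")
    return np.asarray(image) > thresh
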