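"""Image file I/O and resampling.

All images in this package are numpy arrays in RGB channel order with
intensities in [0, 255]: ``uint8`` at file boundaries and pipeline outputs,
``float64`` wherever intermediate precision matters.  Pixel indexing is
0-based ``(row, col)`` with row 0 at the top.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "resize_image"]


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or JPEG file as an H x W x 3 uint8 RGB array.

    Grayscale files are broadcast to three identical channels; an alpha
    channel, if present, is dropped.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the bytes cannot be decoded as an image.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return arr


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB image (or a 2-D mask/grayscale array) to *path*.

    Float values are rounded to the nearest integer and clipped to
    [0, 255] before encoding.  PNG output round-trips losslessly.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def resize_image(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Resample an image to ``height x width`` by bilinear interpolation.

    Pixel centres are aligned (source coordinate ``(i + 0.5) * H / H_out
    - 0.5``, clamped at the borders), with no antialiasing prefilter.
    Output values stay inside the input's per-channel [min, max] by
    convexity of bilinear weights.
    """
    if height <= 0 or width <= 0:
        raise ValueError("target dimensions must be positive")
    arr = np.asarray(image, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    h, w = arr.shape[:2]
    if (h, w) == (height, width):
        out = arr
    else:
        rows = np.clip((np.arange(height) + 0.5) * h / height - 0.5, 0, h - 1)
        cols = np.clip((np.arange(width) + 0.5) * w / width - 0.5, 0, w - 1)
        r0 = np.floor(rows).astype(int)
        c0 = np.floor(cols).astype(int)
        r1 = np.minimum(r0 + 1, h - 1)
        c1 = np.minimum(c0 + 1, w - 1)
        fr = (rows - r0)[:, None, None]
        fc = (cols - c0)[None, :, None]
        out = (
            arr[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
            + arr[np.ix_(r0, c1)] * (1 - fr) * fc
            + arr[np.ix_(r1, c0)] * fr * (1 - fc)
            + arr[np.ix_(r1, c1)] * fr * fc
        )
    if squeeze:
        out = out[:, :, 0]
    if np.asarray(image).dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out
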