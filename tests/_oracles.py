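"""Independent brute-force oracles used by the unit and acceptance tests.

These evaluate operator definitions directly (dense double/quadruple
loops over reflect-padded arrays) and deliberately share no code with
the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def pad_sym(a: np.ndarray, r: int) -> np.ndarray:
    return np.pad(np.asarray(a, dtype=np.float64), r, mode="symmetric")


def gaussian_kernel_2d(kernel_size: int, sigma: float) -> np.ndarray:
    r = (kernel_size - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x * x) / (2.0 * sigma * sigma))
    g /= g.sum()
    return np.outer(g, g)


def conv2_brute(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    r = kernel.shape[0] // 2
    p = pad_sym(img, r)
    h, w = img.shape
    out = np.empty((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(p[i:i + 2 * r + 1, j:j + 2 * r + 1] * kernel)
    return out


def _window_reduce(img: np.ndarray, k: int, fn) -> np.ndarray:
    r = k // 2
    p = pad_sym(img, r)
    h, w = img.shape
    out = np.empty((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            out[i, j] = fn(p[i:i + k, j:j + k])
    return out


def median_brute(img: np.ndarray, k: int) -> np.ndarray:
    return _window_reduce(img, k, np.median)


def _se_reduce(img: np.ndarray, se: np.ndarray, fn) -> np.ndarray:
    k = se.shape[0]
    r = k // 2
    p = pad_sym(img, r)
    h, w = img.shape
    out = np.empty((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            out[i, j] = fn(p[i:i + k, j:j + k][se])
    return out


def dilate_brute(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    return _se_reduce(img, se, np.max)


def erode_brute(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    return _se_reduce(img, se, np.min)


def close_brute(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    return erode_brute(dilate_brute(img, se), se)


def blackhat_brute(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    return close_brute(img, se) - np.asarray(img, dtype=np.float64)


def nl_means_brute(
    v: np.ndarray,
    h: float,
    template_radius: int,
    search_radius: int,
    sigma: float,
    self_weight: str = "max",
) -> np.ndarray:
    """Quadruple-loop windowed non-local means (reflect-padded patches)."""
    v = np.asarray(v, dtype=np.float64)
    r, s = template_radius, search_radius
    hgt, wid = v.shape
    pad = np.pad(v, r + s, mode="symmetric")
    out = np.empty_like(v)
    offset = 2.0 * sigma * sigma
    for i in range(hgt):
        for j in range(wid):
            pi = pad[i + s:i + s + 2 * r + 1, j + s:j + s + 2 * r + 1]
            num = 0.0
            den = 0.0
            wmax = 0.0
            for dy in range(-s, s + 1):
                for dx in range(-s, s + 1):
                    if dy == 0 and dx == 0:
                        continue
                    pj = pad[i + dy + s:i + dy + s + 2 * r + 1,
                             j + dx + s:j + dx + s + 2 * r + 1]
                    dist = np.mean((pi - pj) ** 2)
                    w = np.exp(-max(dist - offset, 0.0) / (h * h))
                    val = pad[i + dy + r + s, j + dx + r + s]
                    num += w * val
                    den += w
                    wmax = max(wmax, w)
            wself = wmax if (self_weight == "max" and wmax > 0) else 1.0
            num += wself * v[i, j]
            den += wself
            out[i, j] = num / den
    return out
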