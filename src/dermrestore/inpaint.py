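"""Fast-marching-method (FMM) image inpainting.

Restores a masked region Omega by traversing it from its boundary inward
in order of arrival time T — the solution of the eikonal equation
``|grad T| = 1`` with ``T = 0`` on the initial boundary — and estimating
each unknown pixel as a normalised weighted sum of the first-order
predictions from its already-known neighbours::

    I(p) = sum_q w(p, q) * [I(q) + grad I(q) . (p - q)] / sum_q w(p, q)

with q ranging over the known pixels of the Chebyshev window B_eps(p).
The weight is the product of three factors: a directional term favouring
pixels along the propagation normal, an inverse-square geometric distance
term, and a level-set term favouring pixels whose arrival time is close
to p's.  Newly inpainted pixels become known for all later pixels, so
information flows from the boundary toward the mask skeleton.

Determinism: ties in the traversal are broken by ``(T, row, col)``
lexicographic order; repeated runs on identical inputs are bit-identical.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KNOWN",
    "BAND",
    "INSIDE",
    "WeightParams",
    "FMMState",
    "eikonal_update",
    "compute_distance_field",
    "weight",
    "inpaint_pixel",
    "inpaint",
]

KNOWN, BAND, INSIDE = 0, 1, 2

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class WeightParams:
    """Scales of the three weight factors.

    epsilon : neighbourhood (Chebyshev) radius of B_eps(p), pixels.
    d0      : geometric-distance reference scale, pixels.
    t0      : level-set-distance reference scale, pixels.
    """

    epsilon: int = 1
    d0: float = 1.0
    t0: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon < 1 or self.d0 <= 0 or self.t0 <= 0:
            raise ValueError("epsilon >= 1 and positive d0, t0 required")


@dataclass
class FMMState:
    """Distance field and flags produced by :func:`compute_distance_field`.

    ``T`` holds the arrival time: positive inside Omega, zero on the
    initial boundary, and the *negated* outward distance on known pixels
    (so the level-set term measures distance between T iso-lines across
    the boundary).  ``flags`` holds the initial labels; ``order`` records
    the traversal sequence of inside pixels for auditing.
    """

    T: np.ndarray
    flags: np.ndarray
    order: list = field(default_factory=list)


def eikonal_update(
    T: np.ndarray, i: int, j: int, known: np.ndarray
) -> float:
    """Quadratic upwind solve of ``|grad T| = 1`` at pixel (i, j).

    Uses the smallest known horizontal and vertical neighbour values; the
    two-sided quadratic applies only when they differ by less than the
    grid step, otherwise the solve degenerates to 1-D (``min + 1``).
    """
    h, w = T.shape
    a = np.inf  # best vertical neighbour
    b = np.inf  # best horizontal neighbour
    if i > 0 and known[i - 1, j]:
        a = T[i - 1, j]
    if i + 1 < h and known[i + 1, j]:
        a = min(a, T[i + 1, j])
    if j > 0 and known[i, j - 1]:
        b = T[i, j - 1]
    if j + 1 < w and known[i, j + 1]:
        b = min(b, T[i, j + 1])
    if not np.isfinite(a) and not np.isfinite(b):
        raise ValueError(f"no usable neighbour at ({i}, {j})")
    if not np.isfinite(a):
        return b + 1.0
    if not np.isfinite(b):
        return a + 1.0
    d = a - b
    if abs(d) >= 1.0:
        return min(a, b) + 1.0
    return 0.5 * (a + b + np.sqrt(2.0 - d * d))


def _march(
    T: np.ndarray,
    frozen: np.ndarray,
    solve: np.ndarray,
    limit: float | None = None,
    order: list | None = None,
) -> None:
    """Propagate T over the ``solve`` region from the frozen set, in place."""
    h, w = T.shape
    heap: list[tuple[float, int, int]] = []
    seeds = np.argwhere(solve & ~frozen)
    for i, j in seeds:
        for di, dj in _N4:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and frozen[ni, nj]:
                t = eikonal_update(T, i, j, frozen)
                if t < T[i, j]:
                    T[i, j] = t
                    heapq.heappush(heap, (t, int(i), int(j)))
                break
    while heap:
        t, i, j = heapq.heappop(heap)
        if frozen[i, j]:
            continue
        if limit is not None and t > limit:
            break
        frozen[i, j] = True
        if order is not None:
            order.append((t, i, j))
        for di, dj in _N4:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and solve[ni, nj] and not frozen[ni, nj]:
                tn = eikonal_update(T, ni, nj, frozen)
                if tn < T[ni, nj]:
                    T[ni, nj] = tn
                    heapq.heappush(heap, (tn, int(ni), int(nj)))


def _initial_boundary(omega: np.ndarray) -> np.ndarray:
    """Known pixels 4-adjacent to Omega (the initial boundary)."""
    h, w = omega.shape
    near = np.zeros_like(omega)
    near[:-1, :] |= omega[1:, :]
    near[1:, :] |= omega[:-1, :]
    near[:, :-1] |= omega[:, 1:]
    near[:, 1:] |= omega[:, :-1]
    return near & ~omega


def compute_distance_field(
    omega: np.ndarray, outside_limit: float = 6.0
) -> FMMState:
    """Arrival-time field T for the masked region and its surroundings.

    T approximates the Euclidean distance from each Omega pixel to the
    initial boundary; on known pixels near the mask the analogous outward
    distance is stored negated (saturated at *outside_limit*), so the
    level-set weight sees a continuous field across the boundary.
    """
    omega = np.asarray(omega, dtype=bool)
    if omega.all():
        raise ValueError("mask covers the whole image; nothing to propagate from")
    flags = np.where(omega, INSIDE, KNOWN).astype(np.uint8)
    boundary = _initial_boundary(omega)
    flags[boundary] = BAND

    T = np.where(omega, np.inf, 0.0)
    order: list = []
    if omega.any():
        frozen = ~omega  # whole known region acts as the zero level set
        _march(T, frozen, solve=omega.copy(), order=order)

        # outward pass: distance of known pixels to the boundary, negated
        tout = np.full(omega.shape, np.inf)
        tout[boundary] = 0.0
        frozen_out = omega | boundary
        _march(tout, frozen_out, solve=~omega, limit=outside_limit)
        tout[~np.isfinite(tout)] = outside_limit
        outside = ~omega & ~boundary
        T[outside] = -tout[outside]
    return FMMState(T=T, flags=flags, order=order)


def _normal_field(T: np.ndarray) -> np.ndarray:
    """Normalised gradient of T (central differences, reflect padding)."""
    pad = np.pad(T, 1, mode="symmetric")
    gr = 0.5 * (pad[2:, 1:-1] - pad[:-2, 1:-1])
    gc = 0.5 * (pad[1:-1, 2:] - pad[1:-1, :-2])
    norm = np.hypot(gr, gc)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(norm > 0, 1.0, 0.0)
        gr = np.where(norm > 0, gr / np.where(norm > 0, norm, 1.0), 0.0) * n
        gc = np.where(norm > 0, gc / np.where(norm > 0, norm, 1.0), 0.0) * n
    return np.stack([gr, gc], axis=-1)


def weight(
    p: tuple[int, int],
    q: tuple[int, int],
    state: FMMState,
    params: WeightParams,
    normal: np.ndarray | None = None,
) -> float:
    """Weight w(p, q) = dir * dst * lev of the known pixel q for target p."""
    if p == q:
        raise ValueError("weight requires p != q")
    dr, dc = p[0] - q[0], p[1] - q[1]
    dist2 = float(dr * dr + dc * dc)
    dist = np.sqrt(dist2)
    if normal is None:
        normal = _normal_field(state.T)
    nr, nc = normal[p[0], p[1]]
    direction = max(abs(dr * nr + dc * nc) / dist, 1e-6)
    dst = params.d0 * params.d0 / dist2
    lev = params.t0 / (params.t0 + abs(state.T[p[0], p[1]] - state.T[q[0], q[1]]))
    return direction * dst * lev


def _image_gradient_at(
    work: np.ndarray, known: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (d/drow, d/dcol) at known pixel (i, j).

    Central differences over known pixels only; one-sided when one side is
    unknown or off-image; zero when both are.
    """
    h, w = known.shape
    val = work[i, j]

    def axis_grad(lo_ok: bool, lo, hi_ok: bool, hi):
        if lo_ok and hi_ok:
            return 0.5 * (hi - lo)
        if hi_ok:
            return hi - val
        if lo_ok:
            return val - lo
        return np.zeros_like(val)

    up_ok = i > 0 and known[i - 1, j]
    dn_ok = i + 1 < h and known[i + 1, j]
    lf_ok = j > 0 and known[i, j - 1]
    rt_ok = j + 1 < w and known[i, j + 1]
    gr = axis_grad(up_ok, work[i - 1, j] if up_ok else None,
                   dn_ok, work[i + 1, j] if dn_ok else None)
    gc = axis_grad(lf_ok, work[i, j - 1] if lf_ok else None,
                   rt_ok, work[i, j + 1] if rt_ok else None)
    return gr, gc


def inpaint_pixel(
    p: tuple[int, int],
    work: np.ndarray,
    known: np.ndarray,
    state: FMMState,
    params: WeightParams,
    normal: np.ndarray | None = None,
) -> np.ndarray:
    """First-order weighted estimate of pixel *p* from known window pixels."""
    h, w = known.shape
    i, j = p
    eps = params.epsilon
    if normal is None:
        normal = _normal_field(state.T)
    num = None
    den = 0.0
    for qi in range(max(0, i - eps), min(h, i + eps + 1)):
        for qj in range(max(0, j - eps), min(w, j + eps + 1)):
            if (qi == i and qj == j) or not known[qi, qj]:
                continue
            wgt = weight(p, (qi, qj), state, params, normal=normal)
            gr, gc = _image_gradient_at(work, known, qi, qj)
            est = work[qi, qj] + gr * (i - qi) + gc * (j - qj)
            num = wgt * est if num is None else num + wgt * est
            den += wgt
    if num is None:
        raise ValueError(f"no known pixel in the window of {p}")
    return np.clip(num / den, 0.0, 255.0)


def inpaint(
    image: np.ndarray,
    omega: np.ndarray,
    params: WeightParams | None = None,
) -> np.ndarray:
    """Inpaint the masked region of an RGB or grayscale image.

    Pixels outside the mask are returned bit-identical to the input;
    masked pixels are filled in non-decreasing arrival-time order, each
    newly filled pixel becoming known for the ones after it.  Channels
    share the traversal and weights but are estimated independently.
    """
    if params is None:
        params = WeightParams()
    omega = np.asarray(omega, dtype=bool)
    arr = np.asarray(image)
    if omega.shape != arr.shape[:2]:
        raise ValueError("mask and image spatial extents differ")
    if not omega.any():
        return arr.copy()

    state = compute_distance_field(omega, outside_limit=params.epsilon + 2.0)
    normal = _normal_field(state.T)
    known = ~omega
    work = arr.astype(np.float64)

    coords = np.argwhere(omega)
    keys = state.T[omega]
    # (T, row, col) lexicographic traversal; argwhere is already row-major
    order = np.argsort(keys, kind="stable")
    prev_t = -np.inf
    for idx in order:
        i, j = map(int, coords[idx])
        t = state.T[i, j]
        assert t >= prev_t - 1e-12, "traversal order must be non-decreasing in T"
        prev_t = t
        work[i, j] = inpaint_pixel((i, j), work, known, state, params, normal=normal)
        known[i, j] = True

    if arr.dtype == np.uint8:
        out = arr.copy()
        out[omega] = np.clip(np.rint(work[omega]), 0, 255).astype(np.uint8)
        return out
    out = arr.astype(np.float64, copy=True)
    out[omega] = work[omega]
    return out
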