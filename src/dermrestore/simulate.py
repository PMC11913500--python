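"""Synthetic dermoscopy corpora: lesion phantoms, hair occlusion, noise.

The generators emulate the two corrupted corpora used to study artifact
impact on lesion classification: a hair corpus (dark curvilinear strands,
thick and thin, superimposed on hair-free images) and a noise corpus
(zero-mean additive Gaussian noise with sigma between 1 and 30).  The
clean images are procedural phantoms — a skin-toned background with
smooth low-frequency texture and an elliptical lesion whose colour and
size family is controlled by a 7-way class label — so paired
(clean, corrupted, truth-mask, label) fixtures exist without any
download, and every pipeline stage can be scored against ground truth.

Every generator is a pure function of its seed: regeneration is
byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .color import to_grayscale
from .filters import blackhat, make_cross_element, threshold_binary
from .io import write_image

__all__ = [
    "NoiseParams",
    "HairParams",
    "LesionPhantomParams",
    "SyntheticPair",
    "CLASS_STYLES",
    "add_gaussian_noise",
    "extract_hair_mask",
    "superimpose_hair",
    "draw_procedural_hairs",
    "generate_lesion_phantom",
    "generate_phantom_corpus",
    "generate_corpus",
]


@dataclass
class NoiseParams:
    """Zero-mean Gaussian noise scale in intensity units (1-30 matches the
    emulated corpora; 0 allowed for identity tests)."""

    sigma: float = 15.0
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class HairParams:
    """Procedural hair-strand geometry.

    n_hairs strands are drawn as quadratic Bezier curves with per-hair
    thickness (px) and dark intensity sampled from the given ranges;
    ``curvature`` scales the control-point jitter relative to the strand
    length.  With ``allow_overlap=False`` the generator retries each
    strand until it does not touch the previous ones.
    """

    n_hairs: int = 15
    thickness_range: tuple[int, int] = (1, 4)
    intensity_range: tuple[int, int] = (10, 90)
    curvature: float = 0.25
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hairs < 0 or self.thickness_range[0] < 1:
            raise ValueError("n_hairs >= 0 and thickness >= 1 required")


# Colour/size families for the seven diagnostic categories.  Colours are
# mutually well separated so the classes are separable by construction.
CLASS_STYLES = (
    {"name": "melanocytic_nevus", "color": (130, 82, 60), "axes": 0.26},
    {"name": "basal_cell_carcinoma", "color": (196, 120, 112), "axes": 0.22},
    {"name": "actinic_keratosis", "color": (205, 165, 120), "axes": 0.30},
    {"name": "melanoma", "color": (52, 32, 30), "axes": 0.32},
    {"name": "benign_keratosis", "color": (115, 75, 35), "axes": 0.20},
    {"name": "dermatofibroma", "color": (96, 52, 92), "axes": 0.16},
    {"name": "vascular_lesion", "color": (172, 40, 60), "axes": 0.24},
)


@dataclass
class LesionPhantomParams:
    """Geometry and palette of one synthetic lesion image."""

    image_size: tuple[int, int] = (64, 64)
    skin_tone: tuple[int, int, int] = (224, 172, 140)
    class_id: int = 0
    lesion_color: tuple[int, int, int] | None = None  # None: class palette
    lesion_axes: tuple[float, float] | None = None  # semi-axes, px
    texture_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.class_id <= 6:
            raise ValueError("class_id must be in [0, 6]")
        h, w = self.image_size
        axes = self.lesion_axes
        if axes is not None and (2 * axes[0] > h or 2 * axes[1] > w):
            raise ValueError("lesion does not fit in the frame")


@dataclass
class SyntheticPair:
    """A clean/corrupted image pair with its ground truth."""

    clean: np.ndarray
    corrupted: np.ndarray
    truth_mask: np.ndarray
    label: int
    provenance: dict = field(default_factory=dict)


def add_gaussian_noise(image: np.ndarray, params: NoiseParams) -> np.ndarray:
    """i.i.d. zero-mean Gaussian noise per pixel per channel, clipped u8."""
    if params.sigma < 0:
        raise ValueError("sigma must be non-negative")
    arr = np.asarray(image, dtype=np.float64)
    if params.sigma == 0 and params.mean == 0:
        return np.asarray(image).copy()
    rng = np.random.default_rng(params.seed)
    noisy = arr + rng.normal(params.mean, params.sigma, size=arr.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def extract_hair_mask(
    donor: np.ndarray, thresh: float = 10.0, min_size: int = 20
) -> np.ndarray:
    """Detect hair in a donor image: blackhat + threshold + speckle guard.

    The same blackhat(cross-11) > thresh detector the dehairing pipeline
    uses, followed by removal of connected components smaller than
    *min_size* pixels.
    """
    gray = to_grayscale(np.asarray(donor))
    response = blackhat(gray, make_cross_element(11))
    mask = threshold_binary(response, thresh, 255)
    labels, n = ndi.label(mask)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size
        keep[0] = False
        mask = keep[labels]
    return mask


def superimpose_hair(
    clean: np.ndarray, donor: np.ndarray, mask: np.ndarray
) -> SyntheticPair:
    """Transplant donor pixels onto *clean* wherever *mask* is true."""
    clean = np.asarray(clean)
    donor = np.asarray(donor)
    mask = np.asarray(mask, dtype=bool)
    if donor.shape != clean.shape or mask.shape != clean.shape[:2]:
        raise ValueError("clean, donor and mask extents must agree")
    corrupted = np.where(mask[:, :, None], donor, clean)
    return SyntheticPair(
        clean=clean.copy(),
        corrupted=corrupted,
        truth_mask=mask.copy(),
        label=-1,
        provenance={"corruption": "hair-donor"},
    )


def _stamp_curve(
    mask: np.ndarray, pts: np.ndarray, radius: float
) -> None:
    """Rasterise a polyline as the union of discs of *radius* (in place)."""
    h, w = mask.shape
    ir = int(np.ceil(radius))
    for y, x in pts:
        yi, xi = int(round(y)), int(round(x))
        y0, y1 = max(0, yi - ir), min(h, yi + ir + 1)
        x0, x1 = max(0, xi - ir), min(w, xi + ir + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - y) ** 2 + (xx - x) ** 2 <= radius**2


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t**2) * p2


def draw_procedural_hairs(
    clean: np.ndarray, params: HairParams
) -> SyntheticPair:
    """Superimpose dark quadratic-Bezier hair strands on a clean image."""
    clean = np.asarray(clean)
    h, w = clean.shape[:2]
    rng = np.random.default_rng(params.seed)
    mask = np.zeros((h, w), dtype=bool)
    corrupted = clean.astype(np.float64).copy()
    hairs = []
    for _ in range(params.n_hairs):
        for _attempt in range(200):
            p0 = rng.uniform([0, 0], [h - 1, w - 1])
            angle = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(0.5, 1.1) * min(h, w)
            p2 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
            mid = 0.5 * (p0 + p2)
            normal = np.array([np.cos(angle), -np.sin(angle)])
            p1 = mid + rng.normal(0, params.curvature * length) * normal
            thickness = int(rng.integers(params.thickness_range[0],
                                         params.thickness_range[1] + 1))
            intensity = float(rng.integers(params.intensity_range[0],
                                           params.intensity_range[1] + 1))
            n_pts = max(8, int(3 * length))
            pts = _bezier_points(p0, p1, p2, n_pts)
            strand = np.zeros_like(mask)
            _stamp_curve(strand, pts, thickness / 2.0)
            if not strand.any():
                continue
            if not params.allow_overlap:
                grown = ndi.binary_dilation(strand, iterations=1)
                if (grown & mask).any():
                    continue
            mask |= strand
            corrupted[strand] = intensity
            hairs.append(
                {"thickness": thickness, "intensity": intensity}
            )
            break
    corrupted = np.clip(np.rint(corrupted), 0, 255).astype(np.uint8)
    corrupted = np.where(mask[:, :, None], corrupted, clean)
    return SyntheticPair(
        clean=clean.copy(),
        corrupted=corrupted,
        truth_mask=mask,
        label=-1,
        provenance={
            "corruption": "hair",
            "n_hairs": len(hairs),
            "hairs": hairs,
            "seed": params.seed,
            "blend": "hard-replacement",
        },
    )


def generate_lesion_phantom(
    params: LesionPhantomParams,
) -> tuple[np.ndarray, int]:
    """One skin phantom: textured background plus a soft-edged ellipse.

    Returns the uint8 RGB image and its class label.
    """
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    style = CLASS_STYLES[params.class_id]
    color = params.lesion_color or style["color"]
    if params.lesion_axes is None:
        base = style["axes"] * min(h, w)
        axes = (base * rng.uniform(0.85, 1.15), base * rng.uniform(0.6, 1.0))
    else:
        axes = params.lesion_axes
    if 2 * axes[0] > h or 2 * axes[1] > w:
        raise ValueError("lesion does not fit in the frame")

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(params.skin_tone, dtype=np.float64)

    if params.texture_scale > 0:
        coarse = rng.normal(0.0, 1.0, size=(max(2, h // 8), max(2, w // 8), 3))
        texture = ndi.zoom(
            coarse, (h / coarse.shape[0], w / coarse.shape[1], 1), order=1
        )[:h, :w]
        img += params.texture_scale * texture

    centre = np.array([h / 2.0, w / 2.0]) + rng.uniform(-0.06, 0.06, 2) * min(h, w)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - centre[0], xx - centre[1]
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    d = np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2)
    alpha = np.clip((1.0 - d) / 0.12, 0.0, 1.0)  # soft edge ~12% of radius
    img = img * (1 - alpha[:, :, None]) + np.asarray(
        color, dtype=np.float64
    ) * alpha[:, :, None]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), params.class_id


def generate_phantom_corpus(
    n_per_class: int = 20,
    image_size: tuple[int, int] = (64, 64),
    seed: int = 0,
    texture_scale: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced in-memory corpus: (n, H, W, 3) uint8 images and labels."""
    images, labels = [], []
    for class_id in range(7):
        for k in range(n_per_class):
            p = LesionPhantomParams(
                image_size=image_size,
                class_id=class_id,
                texture_scale=texture_scale,
                seed=seed * 1_000_003 + class_id * 1009 + k,
            )
            img, lab = generate_lesion_phantom(p)
            images.append(img)
            labels.append(lab)
    return np.stack(images), np.asarray(labels)


def generate_corpus(
    n_per_class: int,
    corruption: str,
    out_dir: str | os.PathLike,
    seed: int = 0,
    image_size: tuple[int, int] = (64, 64),
) -> pd.DataFrame:
    """Write a clean/corrupted/masks PNG tree plus a CSV manifest.

    ``corruption`` is ``"hair"``, ``"noise"`` or ``"none"``.  Per-image
    noise sigma is drawn uniformly from [1, 30]; hair counts from
    [15, 25].  Returns the manifest DataFrame (also written as
    ``manifest.csv``).
    """
    if corruption not in ("hair", "noise", "none"):
        raise ValueError("corruption must be 'hair', 'noise' or 'none'")
    out_dir = os.fspath(out_dir)
    os.makedirs(os.path.join(out_dir, "clean"), exist_ok=True)
    if corruption != "none":
        os.makedirs(os.path.join(out_dir, "corrupted"), exist_ok=True)
    if corruption == "hair":
        os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)

    images, labels = generate_phantom_corpus(
        n_per_class, image_size=image_size, seed=seed
    )
    rng = np.random.default_rng((seed * 2_654_435_761 + 777) % (2**31))
    rows = []
    for idx, (img, lab) in enumerate(zip(images, labels)):
        name = f"{idx:04d}.png"
        write_image(img, os.path.join(out_dir, "clean", name))
        row = {
            "file": name,
            "label": int(lab),
            "corruption": corruption,
            "sigma": np.nan,
            "n_hairs": np.nan,
            "seed": int(seed),
        }
        if corruption == "noise":
            sigma = float(rng.uniform(1.0, 30.0))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            noisy = add_gaussian_noise(img, NoiseParams(sigma=sigma, seed=sub_seed))
            write_image(noisy, os.path.join(out_dir, "corrupted", name))
            row["sigma"] = sigma
        elif corruption == "hair":
            n_hairs = int(rng.integers(15, 26))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            pair = draw_procedural_hairs(
                img, HairParams(n_hairs=n_hairs, seed=sub_seed)
            )
            write_image(pair.corrupted, os.path.join(out_dir, "corrupted", name))
            write_image(
                pair.truth_mask.astype(np.uint8) * 255,
                os.path.join(out_dir, "masks", name),
            )
            row["n_hairs"] = n_hairs
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
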