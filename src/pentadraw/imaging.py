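"""Image preparation and augmentation for drawing-to-score models.

The preparation chain mirrors how scanned drawing-test forms are made
model-ready: remove digitization specks by morphological opening, locate
the drawing, pad it onto a fixed 500x500 white canvas without rescaling
(so drawing size stays informative), and resize to the 224x224 input of
standard vision backbones.  The augmentation suite applies mild,
label-preserving perturbations (flips, rotation, translation, contrast /
brightness / sharpness, Gaussian and salt-and-pepper noise) in randomized
order; :func:`tta_score` averages any image-to-score function over such
variants.

The region detector here is a contour-based reference implementation (the
bounding box of the largest ink component plus a margin); any function
with the same signature can be swapped in, e.g. a learned detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, ImageEnhance
from scipy import ndimage as ndi
from skimage import morphology as skmorph

from .simulator import RasterImage

__all__ = [
    "BoundingBox",
    "AugmentConfig",
    "AugmentPlan",
    "DetectionError",
    "denoise_opening",
    "detect_pentagon_region",
    "standardize",
    "resize_for_model",
    "augment",
    "tta_score",
    "prepare",
]

logger = logging.getLogger(__name__)


class DetectionError(ValueError):
    """Raised when no drawing can be located in an image."""


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [x_min, x_max) x [y_min, y_max)."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError(f"empty bounding box {self}")
        if min(self.x_min, self.y_min) < 0:
            raise ValueError(f"negative bounding box corner {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min


def denoise_opening(img: RasterImage, kernel_size: int = 3) -> RasterImage:
    """Morphological opening of the ink foreground.

    Erosion followed by dilation with a square structuring element:
    isolated specks smaller than the kernel disappear, strokes at least as
    wide survive.  Idempotent.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be a positive odd integer")
    if kernel_size == 1:
        return img
    ink = 255 - img.pixels  # work on the ink foreground
    footprint = np.ones((kernel_size, kernel_size), dtype=bool)
    opened = skmorph.opening(ink, footprint)
    return RasterImage(255 - opened)


def detect_pentagon_region(img: RasterImage, margin: float = 0.05) -> BoundingBox:
    """Bounding box of the largest ink component, expanded by ``margin``.

    The margin is a fraction of the box size on each side, clipped to the
    image.  Raises :class:`DetectionError` on blank images (mirroring the
    manual filter for forms without a drawing).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    ink = img.ink_mask()
    if not ink.any():
        raise DetectionError("no ink found: image appears blank")
    lab, n = ndi.label(ink, structure=np.ones((3, 3)))
    if n == 0:
        raise DetectionError("no ink found: image appears blank")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    # cover the largest component and any component at least 5% its size
    # (the two pentagons can be disjoint components)
    big = sizes.max()
    mask = np.isin(lab, [i + 1 for i in range(n) if sizes[i] >= 0.05 * big])
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    y0, y1 = int(rows[0]), int(rows[-1]) + 1
    x0, x1 = int(cols[0]), int(cols[-1]) + 1
    my = int(round(margin * (y1 - y0)))
    mx = int(round(margin * (x1 - x0)))
    return BoundingBox(
        x_min=max(0, x0 - mx),
        y_min=max(0, y0 - my),
        x_max=min(img.width, x1 + mx),
        y_max=min(img.height, y1 + my),
    )


def standardize(img: RasterImage, box: BoundingBox,
                size: int = 500) -> RasterImage:
    """Pad the cropped drawing onto a white ``size`` x ``size`` canvas.

    The crop is centered and *not* rescaled, preserving the drawn size.
    Crops larger than the canvas are isotropically downscaled to fit (with
    a logged warning), since padding alone cannot contain them.
    """
    if (box.x_max > img.width or box.y_max > img.height):
        raise ValueError(f"box {box} exceeds image {img.width}x{img.height}")
    crop = img.pixels[box.y_min:box.y_max, box.x_min:box.x_max]
    h, w = crop.shape
    if h > size or w > size:
        scale = size / max(h, w)
        new_w, new_h = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
        logger.warning(
            "crop %dx%d exceeds %dx%d canvas; downscaling isotropically",
            w, h, size, size,
        )
        crop = np.asarray(
            Image.fromarray(crop).resize((new_w, new_h),
                                         resample=Image.Resampling.BILINEAR),
            dtype=np.uint8,
        )
        h, w = crop.shape
    canvas = np.full((size, size), 255, dtype=np.uint8)
    y0 = (size - h) // 2
    x0 = (size - w) // 2
    canvas[y0:y0 + h, x0:x0 + w] = crop
    return RasterImage(canvas)


def resize_for_model(img: RasterImage, size: int = 224) -> RasterImage:
    """Bilinear resize to the model input resolution (no-op if already there)."""
    if img.width == size and img.height == size:
        return img
    out = img.to_pil().resize((size, size), resample=Image.Resampling.BILINEAR)
    return RasterImage.from_pil(out)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Transform inclusion probabilities and parameter ranges.

    Ranges are half-widths around the identity; each enabled transform is
    included with its probability and the applied order is randomized.
    """

    p_hflip: float = 0.25
    p_vflip: float = 0.0
    p_rotate: float = 0.5
    rotate_deg: float = 15.0
    p_translate: float = 0.5
    translate_frac: float = 0.05
    p_contrast: float = 0.5
    contrast_frac: float = 0.2
    p_brightness: float = 0.5
    brightness_frac: float = 0.2
    p_sharpness: float = 0.5
    sharpness_range: Tuple[float, float] = (0.5, 1.5)
    p_gauss_noise: float = 0.25
    gauss_sigma_max: float = 10.0
    p_salt_pepper: float = 0.25
    salt_pepper_max: float = 0.005

    @classmethod
    def identity(cls) -> "AugmentConfig":
        """A config that never applies any transform (for TTA sanity checks)."""
        return cls(p_hflip=0, p_vflip=0, p_rotate=0, p_translate=0,
                   p_contrast=0, p_brightness=0, p_sharpness=0,
                   p_gauss_noise=0, p_salt_pepper=0)

    def transform_names(self) -> Tuple[str, ...]:
        return ("hflip", "vflip", "rotate", "translate", "contrast",
                "brightness", "sharpness", "gauss_noise", "salt_pepper")


@dataclass(frozen=True)
class AugmentPlan:
    """Ordered record of the transforms actually applied to one image."""

    steps: Tuple[Tuple[str, Dict[str, float]], ...]


def _apply_transform(px: np.ndarray, name: str, params: Dict[str, float]
                     ) -> np.ndarray:
    im = Image.fromarray(px)
    if name == "hflip":
        im = im.transpose(Image.Transpose.FLIP_LEFT_RIGHT)
    elif name == "vflip":
        im = im.transpose(Image.Transpose.FLIP_TOP_BOTTOM)
    elif name == "rotate":
        im = im.rotate(params["deg"], resample=Image.Resampling.BILINEAR,
                       fillcolor=255)
    elif name == "translate":
        im = im.transform(
            im.size, Image.Transform.AFFINE,
            (1, 0, params["dx"], 0, 1, params["dy"]),
            resample=Image.Resampling.BILINEAR, fillcolor=255)
    elif name == "contrast":
        im = ImageEnhance.Contrast(im).enhance(params["factor"])
    elif name == "brightness":
        im = ImageEnhance.Brightness(im).enhance(params["factor"])
    elif name == "sharpness":
        im = ImageEnhance.Sharpness(im).enhance(params["factor"])
    elif name == "gauss_noise":
        arr = np.asarray(im, dtype=float)
        rng = np.random.default_rng(int(params["noise_seed"]))
        arr = arr + rng.normal(0, params["sigma"], size=arr.shape)
        return np.clip(arr, 0, 255).astype(np.uint8)
    elif name == "salt_pepper":
        arr = np.asarray(im).copy()
        rng = np.random.default_rng(int(params["noise_seed"]))
        n_px = int(params["fraction"] * arr.size)
        if n_px:
            idx = rng.integers(0, arr.size, size=n_px)
            vals = rng.integers(0, 2, size=n_px) * 255
            arr.flat[idx] = vals
        return arr.astype(np.uint8)
    else:  # pragma: no cover
        raise ValueError(f"unknown transform {name}")
    return np.asarray(im, dtype=np.uint8)


def augment(img: RasterImage, config: Optional[AugmentConfig] = None,
            rng: Optional[np.random.Generator] = None
            ) -> Tuple[RasterImage, AugmentPlan]:
    """Apply the enabled transforms in randomized order.

    Deterministic given the generator state; returns the transformed image
    and a plan record sufficient to describe what was applied.
    """
    config = config or AugmentConfig()
    if not config.transform_names():
        raise ValueError("empty transform set")
    rng = rng if rng is not None else np.random.default_rng()
    candidates: List[Tuple[str, Dict[str, float]]] = []
    # sample inclusion and parameters in a fixed name order so that the
    # consumed randomness is reproducible, then shuffle the applied order
    for name in config.transform_names():
        p = getattr(config, f"p_{name}")
        include = rng.uniform() < p
        params: Dict[str, float] = {}
        if name == "rotate":
            params["deg"] = float(rng.uniform(-config.rotate_deg,
                                              config.rotate_deg))
        elif name == "translate":
            lim = config.translate_frac
            params["dx"] = float(rng.uniform(-lim, lim) * img.width)
            params["dy"] = float(rng.uniform(-lim, lim) * img.height)
        elif name == "contrast":
            params["factor"] = float(1 + rng.uniform(-config.contrast_frac,
                                                     config.contrast_frac))
        elif name == "brightness":
            params["factor"] = float(1 + rng.uniform(-config.brightness_frac,
                                                     config.brightness_frac))
        elif name == "sharpness":
            lo, hi = config.sharpness_range
            params["factor"] = float(rng.uniform(lo, hi))
        elif name == "gauss_noise":
            params["sigma"] = float(rng.uniform(0, config.gauss_sigma_max))
            params["noise_seed"] = int(rng.integers(0, 2**31))
        elif name == "salt_pepper":
            params["fraction"] = float(rng.uniform(0, config.salt_pepper_max))
            params["noise_seed"] = int(rng.integers(0, 2**31))
        if include:
            candidates.append((name, params))
    order = rng.permutation(len(candidates))
    px = img.pixels
    steps: List[Tuple[str, Dict[str, float]]] = []
    for i in order:
        name, params = candidates[int(i)]
        px = _apply_transform(px, name, params)
        steps.append((name, params))
    return RasterImage(px), AugmentPlan(steps=tuple(steps))


def tta_score(
    scorer: Callable[[RasterImage], float],
    img: RasterImage,
    n_variants: int = 30,
    rng: Optional[np.random.Generator] = None,
    config: Optional[AugmentConfig] = None,
) -> float:
    """Test-time augmentation: mean of ``scorer`` over augmented variants.

    With the identity config this equals ``scorer(img)`` for any
    ``n_variants``.  Non-finite scorer output raises, naming the variant.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    total = 0.0
    for i in range(n_variants):
        variant, _ = augment(img, config, rng)
        val = float(scorer(variant))
        if not np.isfinite(val):
            raise ValueError(f"scorer returned non-finite value on variant {i}")
        total += val
    return total / n_variants


def prepare_steps(
    img: RasterImage, kernel_size: int = 3, margin: float = 0.05,
    detector: Optional[Callable[[RasterImage, float], BoundingBox]] = None,
) -> Tuple[RasterImage, BoundingBox, RasterImage, RasterImage]:
    """Preparation chain with intermediates: (denoised, box, 500x500, 224x224).

    If the opening erases the whole drawing (feather-thin strokes below the
    kernel size), detection falls back to the un-denoised image so the
    chain still completes; the opening's contract is to remove features
    smaller than its kernel, which must not turn into a hard failure for
    thin but real drawings.
    """
    detector = detector or detect_pentagon_region
    den = denoise_opening(img, kernel_size)
    try:
        box = detector(den, margin)
    except DetectionError:
        logger.warning("opening erased all ink; detecting on raw image")
        den = img
        box = detector(den, margin)
    std = standardize(den, box)
    return den, box, std, resize_for_model(std)


def prepare(img: RasterImage, kernel_size: int = 3, margin: float = 0.05,
            detector: Optional[Callable[[RasterImage, float], BoundingBox]] = None
            ) -> RasterImage:
    """Full preparation chain: denoise, detect, standardize, resize."""
    return prepare_steps(img, kernel_size, margin, detector)[3]
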