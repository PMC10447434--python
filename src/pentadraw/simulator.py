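"""Render parametrized intersecting-pentagon drawings to raster images.

The simulator turns a :class:`~pentadraw.geometry.PentagonSpec` into a
500x500 8-bit grayscale image (white paper, dark ink) through a fully
seeded chain: place the two polygons, jitter their vertex angles, replace
every edge by a wavy hand-drawn path, and rasterize the two closed strokes
with anti-aliasing.  Sweep generation reproduces the explainability
protocol: for one attribute, eight levels times a number of replicates,
with the remaining attributes jittered in a small window around the ideal
drawing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw

from .geometry import (
    IDEAL_SPEC,
    PentagonSpec,
    Polygon,
    distort_angles,
    place_pentagons,
    polygon_area,
    polygon_intersection_area,
)

__all__ = [
    "PolylineDrawing",
    "RasterImage",
    "JitterConfig",
    "GroundTruth",
    "wavy_path",
    "render",
    "generate",
    "sweep_images",
    "DEFAULT_SWEEP_LEVELS",
    "SWEEP_ATTRIBUTES",
]

INK_THRESHOLD = 128  # pixels darker than this count as ink
_SUPERSAMPLE = 4


@dataclass(frozen=True)
class RasterImage:
    """8-bit grayscale canvas: white (255) background, dark ink."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def ink_mask(self, threshold: int = INK_THRESHOLD) -> np.ndarray:
        return self.pixels < threshold

    @property
    def ink_fraction(self) -> float:
        return float(self.ink_mask().mean())

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels, mode="L")

    @classmethod
    def from_pil(cls, im: Image.Image) -> "RasterImage":
        return cls(np.asarray(im.convert("L"), dtype=np.uint8))

    def save(self, path) -> None:
        self.to_pil().save(path, format="PNG")

    @classmethod
    def load(cls, path) -> "RasterImage":
        with Image.open(path) as im:
            return cls.from_pil(im)

    @classmethod
    def blank(cls, width: int = 500, height: int = 500) -> "RasterImage":
        return cls(np.full((height, width), 255, dtype=np.uint8))


@dataclass(frozen=True)
class PolylineDrawing:
    """Vector strokes of the two figures prior to rasterization."""

    strokes: Tuple[np.ndarray, ...]
    canvas_size: Tuple[int, int] = (500, 500)
    spec: PentagonSpec | None = None

    def __post_init__(self) -> None:
        strokes = tuple(np.asarray(s, dtype=float) for s in self.strokes)
        if not strokes:
            raise ValueError("drawing needs at least one stroke")
        for s in strokes:
            if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 4:
                raise ValueError("each stroke needs an (n>=4, 2) point array")
            if not np.allclose(s[0], s[-1]):
                raise ValueError("strokes must be closed (first point == last)")
        object.__setattr__(self, "strokes", strokes)


@dataclass(frozen=True)
class GroundTruth:
    """Per-image truth record: the spec and exact post-distortion geometry."""

    spec: PentagonSpec
    polygon_a: Polygon
    polygon_b: Polygon
    overlap_area: float
    overlap_fraction: float

    def as_row(self) -> Dict[str, float]:
        row = {name: getattr(self.spec, name) for name in PentagonSpec.ATTRIBUTES}
        row["seed"] = self.spec.seed
        row["overlap_fraction"] = self.overlap_fraction
        row["overlap_area"] = self.overlap_area
        return row


@dataclass(frozen=True)
class JitterConfig:
    """Nuisance perturbation half-widths around the ideal drawing.

    During a sweep each non-swept attribute is drawn uniformly from
    ``ideal +/- half_width``, clipped to its valid domain; attributes whose
    ideal sits on a domain boundary (distortion, waviness) therefore jitter
    one-sidedly.  Vertex counts are never jittered.
    """

    distance: float = 0.05
    alignment: float = 0.028  # ~2 degrees of pentagon phase
    angle_distortion: float = 0.02
    size_equality: float = 0.05
    size: float = 0.03
    line_width: float = 0.5
    waviness: float = 0.01
    replicates: int = 20

    def __post_init__(self) -> None:
        for name in ("distance", "alignment", "angle_distortion",
                     "size_equality", "size", "line_width", "waviness"):
            if getattr(self, name) < 0:
                raise ValueError(f"jitter half-width {name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def perturb(self, base: PentagonSpec, rng: np.random.Generator,
                frozen: Sequence[str] = ()) -> Dict[str, float]:
        """Sample jittered attribute values (excluding ``frozen`` ones)."""
        out: Dict[str, float] = {}
        bounds = {
            "distance": (0.0, 2.0),
            "alignment": (0.0, 1.0),
            "angle_distortion": (0.0, 1.0),
            "size_equality": (0.05, 2.0),
            "size": (0.02, 0.55),
            "line_width": (1.0, 20.0),
            "waviness": (0.0, 0.3),
        }
        for name, (lo, hi) in bounds.items():
            if name in frozen:
                continue
            hw = getattr(self, name)
            val = getattr(base, name) + rng.uniform(-hw, hw)
            out[name] = float(np.clip(val, lo, hi))
        return out


SWEEP_ATTRIBUTES = (
    "n_vertices",
    "distance",
    "alignment",
    "angle_distortion",
    "size_equality",
    "size",
    "line_width",
    "waviness",
)

# Eight levels per attribute, spanning the pass and fail regimes of the
# drawing test.  "n_vertices" sweeps both figures' counts together.
DEFAULT_SWEEP_LEVELS: Dict[str, Tuple[float, ...]] = {
    "n_vertices": (3, 4, 5, 6, 7, 8, 9, 10),
    "distance": (0.0, 0.25, 0.5, 0.75, 1.0, 1.1, 1.25, 1.5),
    "alignment": tuple(0.5 * k / 7 for k in range(8)),
    "angle_distortion": (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35),
    "size_equality": tuple(np.round(np.linspace(0.2, 1.8, 8), 4)),
    "size": (0.05, 0.1, 0.15, 0.2, 0.27, 0.35, 0.43, 0.5),
    "line_width": (1, 3, 5, 7, 9, 11, 13, 15),
    "waviness": (0.0, 0.017, 0.034, 0.051, 0.069, 0.086, 0.103, 0.12),
}

_ALIASES = {
    "number of vertices": "n_vertices",
    "vertices": "n_vertices",
    "distance between pentagons": "distance",
    "alignment of two pentagons": "alignment",
    "angle distortion": "angle_distortion",
    "size equality": "size_equality",
    "pentagon size": "size",
    "line width": "line_width",
    "line waviness": "waviness",
}


def canonical_attribute(name: str) -> str:
    key = name.strip().lower().replace("-", " ")
    key = _ALIASES.get(key, key.replace(" ", "_"))
    if key not in SWEEP_ATTRIBUTES:
        raise ValueError(
            f"unknown attribute {name!r}; valid: {', '.join(SWEEP_ATTRIBUTES)}"
        )
    return key


def wavy_path(
    p0: Sequence[float],
    p1: Sequence[float],
    waviness: float,
    n_points: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """A hand-tremor path from p0 to p1.

    The straight chord is displaced perpendicularly by a sum of three
    random-phase sinusoids, windowed by ``4 t (1 - t)`` so the endpoints
    stay exact, then rescaled so the RMS displacement over the sampled
    points equals ``waviness * |p1 - p0|``.
    """
    if waviness < 0:
        raise ValueError("waviness must be >= 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    chord = p1 - p0
    length = float(np.linalg.norm(chord))
    if length < 1e-12:
        raise ValueError("coincident endpoints")
    t = np.linspace(0.0, 1.0, n_points)
    base = p0[None, :] + t[:, None] * chord[None, :]
    if waviness == 0:
        return base
    amps = rng.uniform(0.5, 1.0, size=3)
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    disp = np.zeros_like(t)
    for k in range(3):
        disp += amps[k] * np.sin(2 * np.pi * (k + 1) * t + phases[k])
    disp *= 4 * t * (1 - t)
    rms = float(np.sqrt(np.mean(disp**2)))
    if rms > 1e-12:
        disp *= (waviness * length) / rms
    normal = np.array([-chord[1], chord[0]]) / length
    return base + disp[:, None] * normal[None, :]


def _polygon_strokes(
    poly: Polygon, waviness: float, rng: np.random.Generator
) -> np.ndarray:
    """Closed wavy stroke tracing the polygon edge by edge."""
    pts: List[np.ndarray] = []
    v = poly.vertices
    for i in range(poly.n):
        a, b = v[i], v[(i + 1) % poly.n]
        n_pts = max(9, int(np.linalg.norm(b - a) / 3.0))
        seg = wavy_path(a, b, waviness, n_pts, rng)
        pts.append(seg[:-1] if i < poly.n - 1 else seg)
    stroke = np.vstack(pts)
    stroke = np.vstack([stroke, stroke[:1]]) if not np.allclose(
        stroke[0], stroke[-1]) else stroke
    return stroke


def render(drawing: PolylineDrawing, line_width: float) -> RasterImage:
    """Rasterize the strokes: anti-aliased dark ink on a white canvas.

    Drawn at 4x supersampling and box-downsampled, so output is
    deterministic and ink coverage grows strictly with line width.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1 pixel")
    w, h = drawing.canvas_size
    for s in drawing.strokes:
        bad = (s[:, 0] < 0) | (s[:, 0] >= w) | (s[:, 1] < 0) | (s[:, 1] >= h)
        if np.any(bad):
            x, y = s[np.argmax(bad)]
            raise ValueError(f"stroke exits canvas at ({x:.1f}, {y:.1f})")
    ss = _SUPERSAMPLE
    im = Image.new("L", (w * ss, h * ss), color=255)
    draw = ImageDraw.Draw(im)
    px_width = max(1, int(round(line_width * ss)))
    for s in drawing.strokes:
        coords = [(float(x) * ss, float(y) * ss) for x, y in s]
        draw.line(coords, fill=0, width=px_width, joint="curve")
    im = im.resize((w, h), resample=Image.Resampling.BOX)
    return RasterImage.from_pil(im)


def build_drawing(spec: PentagonSpec,
                  canvas_size: Tuple[int, int] = (500, 500)
                  ) -> Tuple[PolylineDrawing, GroundTruth]:
    """Vector stage of :func:`generate`: placed, distorted, wavy strokes."""
    rng = np.random.default_rng(spec.seed)
    poly_a, poly_b = place_pentagons(spec, canvas_size)
    poly_a = distort_angles(poly_a, spec.angle_distortion, rng)
    poly_b = distort_angles(poly_b, spec.angle_distortion, rng)
    stroke_a = _polygon_strokes(poly_a, spec.waviness, rng)
    stroke_b = _polygon_strokes(poly_b, spec.waviness, rng)
    inter = polygon_intersection_area(poly_a, poly_b)
    smaller = min(polygon_area(poly_a), polygon_area(poly_b))
    truth = GroundTruth(
        spec=spec,
        polygon_a=poly_a,
        polygon_b=poly_b,
        overlap_area=inter,
        overlap_fraction=inter / smaller,
    )
    drawing = PolylineDrawing(
        strokes=(stroke_a, stroke_b), canvas_size=canvas_size, spec=spec
    )
    return drawing, truth


def generate(spec: PentagonSpec,
             canvas_size: Tuple[int, int] = (500, 500)
             ) -> Tuple[RasterImage, GroundTruth]:
    """Render one drawing; a pure function of the spec (seed included)."""
    drawing, truth = build_drawing(spec, canvas_size)
    return render(drawing, spec.line_width), truth


def child_seed(base_seed: int, *parts) -> int:
    """Stable child seed from a base seed and arbitrary labels."""
    tag = "|".join([str(base_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.blake2b(tag, digest_size=4).digest(), "big") % (2**31)


def _spec_at_level(attribute: str, level: float,
                   jitter: JitterConfig, seed: int) -> PentagonSpec:
    rng = np.random.default_rng(seed)
    if attribute == "n_vertices":
        frozen: Tuple[str, ...] = ()
        overrides = {"n_vertices_a": int(level), "n_vertices_b": int(level)}
    else:
        frozen = (attribute,)
        overrides = {attribute: float(level) if attribute != "line_width"
                     else float(level)}
    nuisance = jitter.perturb(IDEAL_SPEC, rng, frozen=frozen)
    nuisance.update(overrides)
    return IDEAL_SPEC.with_(seed=seed, **nuisance)


def sweep_images(
    attribute: str,
    levels: Sequence[float] | None = None,
    jitter: JitterConfig | None = None,
    base_seed: int = 0,
) -> List[Tuple[float, RasterImage, GroundTruth]]:
    """Generate the 8-level x N-replicate image set for one attribute.

    Within a level only the nuisance attributes vary; the swept attribute
    is held at the level value.  Every image's seed derives
    deterministically from ``(base_seed, attribute, level index, replicate
    index)``, so the whole set is reproducible.
    """
    attribute = canonical_attribute(attribute)
    if levels is None:
        levels = DEFAULT_SWEEP_LEVELS[attribute]
    levels = tuple(levels)
    if len(levels) != 8:
        raise ValueError(f"expected exactly 8 levels, got {len(levels)}")
    jitter = jitter or JitterConfig()
    out: List[Tuple[float, RasterImage, GroundTruth]] = []
    for li, level in enumerate(levels):
        for ri in range(jitter.replicates):
            seed = child_seed(base_seed, attribute, li, ri)
            spec = _spec_at_level(attribute, level, jitter, seed)
            img, truth = generate(spec)
            out.append((float(level), img, truth))
    return out
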