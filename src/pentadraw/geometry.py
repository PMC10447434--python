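"""Exact vector geometry for the intersecting-pentagon stimulus.

All geometry lives in canvas pixel coordinates: origin at the top-left
corner, x increasing rightward, y increasing downward.  Polygons are stored
counter-clockwise *in this frame* (which looks clockwise on screen), so the
same arrays can be rasterized without axis flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Polygon",
    "PentagonSpec",
    "IDEAL_SPEC",
    "make_regular_polygon",
    "distort_angles",
    "polygon_area",
    "polygon_intersection_area",
    "place_pentagons",
]


@dataclass(frozen=True)
class Polygon:
    """A closed polygon given by its ordered vertices.

    Vertices are stored as an (n, 2) float array, counter-clockwise in the
    canvas frame (y down).  Construction rejects degenerate inputs:
    fewer than three vertices or repeated consecutive vertices.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs an (n>=3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("polygon vertices must be finite")
        gaps = np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1)
        if np.any(gaps < 1e-12):
            raise ValueError("consecutive vertices coincide")
        # normalise orientation to CCW (positive signed area in y-down frame)
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    @property
    def n(self) -> int:
        return self.vertices.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edge_lengths(self) -> np.ndarray:
        v = self.vertices
        return np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class PentagonSpec:
    """The eight drawing attributes plus a seed.

    Attributes mirror the drawing features a rater attends to: vertex counts
    of both figures, center distance (as a fraction of the sum of the two
    circumradii), rotational alignment of the right figure (0 = vertex
    facing vertex, 0.5 = vertex facing side), angular jitter of the vertex
    positions, circumradius ratio, overall size (circumradius of the left
    figure as a fraction of the canvas half-width), stroke width in pixels,
    and edge waviness (RMS perpendicular displacement per unit edge length).
    """

    n_vertices_a: int = 5
    n_vertices_b: int = 5
    distance: float = 0.75
    alignment: float = 0.0
    angle_distortion: float = 0.0
    size_equality: float = 1.0
    size: float = 0.35
    line_width: float = 3.0
    waviness: float = 0.0
    seed: int = 0

    ATTRIBUTES = (
        "n_vertices_a",
        "n_vertices_b",
        "distance",
        "alignment",
        "angle_distortion",
        "size_equality",
        "size",
        "line_width",
        "waviness",
    )

    def __post_init__(self) -> None:
        for name in self.ATTRIBUTES:
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val!r}")
        for name in ("n_vertices_a", "n_vertices_b"):
            n = getattr(self, name)
            if int(n) != n or not (3 <= n <= 10):
                raise ValueError(f"{name} must be an integer in [3, 10], got {n!r}")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if not (0 < self.size_equality <= 2):
            raise ValueError("size_equality must lie in (0, 2]")
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.line_width < 1:
            raise ValueError("line_width must be >= 1 pixel")
        if self.angle_distortion < 0 or self.waviness < 0:
            raise ValueError("angle_distortion and waviness must be >= 0")

    def with_(self, **kwargs) -> "PentagonSpec":
        return replace(self, **kwargs)


IDEAL_SPEC = PentagonSpec()


def make_regular_polygon(
    n: int,
    circumradius: float,
    center: Tuple[float, float] = (0.0, 0.0),
    phase: float = 0.0,
) -> Polygon:
    """Regular n-gon on the circle of the given radius.

    ``phase`` is the polar angle of the first vertex; phase 0 points along
    +x.  Vertices are emitted in order of increasing polar angle, which is
    counter-clockwise in the y-down canvas frame.
    """
    if int(n) != n or n < 3:
        raise ValueError(f"need an integer n >= 3, got {n!r}")
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    theta = phase + 2 * np.pi * np.arange(n) / n
    cx, cy = center
    verts = np.column_stack([cx + circumradius * np.cos(theta),
                             cy + circumradius * np.sin(theta)])
    return Polygon(verts)


def distort_angles(p: Polygon, scale: float, rng: np.random.Generator) -> Polygon:
    """Jitter each vertex's polar angle about the polygon centroid.

    The perturbations are zero-mean Gaussian with standard deviation
    ``scale * 2*pi/n`` and are clamped to 45% of the nominal angular
    spacing, so the cyclic vertex order (and hence simple-polygon-ness for
    near-regular inputs) is preserved.  Radii are untouched: distortion is
    orthogonal to size.  ``scale = 0`` returns the polygon unchanged.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if scale == 0:
        return p
    c = p.centroid
    rel = p.vertices - c
    radii = np.linalg.norm(rel, axis=1)
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    spacing = 2 * np.pi / p.n
    jitter = rng.normal(0.0, scale * spacing, size=p.n)
    jitter = np.clip(jitter, -0.45 * spacing, 0.45 * spacing)
    angles = angles + jitter
    verts = c + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return Polygon(verts)


def polygon_area(p: Polygon) -> float:
    """Absolute (orientation-independent) area, by the shoelace formula."""
    v = p.vertices
    if np.unique(np.round(v, 12), axis=0).shape[0] < 3:
        raise ValueError("degenerate polygon: fewer than 3 distinct points")
    return abs(_signed_area(v))


def polygon_intersection_area(a: Polygon, b: Polygon) -> float:
    """Area of the geometric intersection of two simple polygons.

    Exact for convex and non-convex inputs; returns 0 for disjoint pairs.
    """
    sa, sb = a.to_shapely(), b.to_shapely()
    if not sa.is_valid:
        sa = sa.buffer(0)
    if not sb.is_valid:
        sb = sb.buffer(0)
    return float(sa.intersection(sb).area)


def place_pentagons(
    spec: PentagonSpec,
    canvas_size: Tuple[int, int] = (500, 500),
) -> Tuple[Polygon, Polygon]:
    """Lay out the two figures side by side on the canvas midline.

    Figure A sits left of the canvas center, figure B right; the pair is
    centered horizontally.  The center separation is
    ``spec.distance * (r_a + r_b)``.  A's phase points its first vertex at
    B (along +x) and B's points back at A, so ``alignment = 0`` is the
    vertex-to-vertex configuration; ``alignment`` rotates B by that
    fraction of its own vertex spacing, with 0.5 giving vertex-to-side.
    """
    w, h = canvas_size
    r_a = spec.size * (w / 2.0)
    r_b = r_a * spec.size_equality
    sep = spec.distance * (r_a + r_b)
    cy = h / 2.0
    cx = w / 2.0
    center_a = (cx - sep / 2.0, cy)
    center_b = (cx + sep / 2.0, cy)
    # A's first vertex points right (+x, toward B); B's points left (toward A)
    poly_a = make_regular_polygon(spec.n_vertices_a, r_a, center_a, phase=0.0)
    phase_b = np.pi + spec.alignment * (2 * np.pi / spec.n_vertices_b)
    poly_b = make_regular_polygon(spec.n_vertices_b, r_b, center_b, phase=phase_b)
    return poly_a, poly_b


def pixel_intersection_area(
    a: Polygon, b: Polygon, resolution: int = 2000
) -> float:
    """Rasterization estimate of the intersection area (oracle for tests).

    Both polygons are drawn as filled masks on a common ``resolution``-wide
    grid covering their joint bounding box; the overlap pixel count is
    scaled back to geometry units.
    """
    from skimage.draw import polygon as _draw_polygon

    pts = np.vstack([a.vertices, b.vertices])
    lo = pts.min(axis=0) - 1.0
    hi = pts.max(axis=0) + 1.0
    span = float(max(hi - lo))
    scale = (resolution - 1) / span

    def mask(p: Polygon) -> np.ndarray:
        v = (p.vertices - lo) * scale
        m = np.zeros((resolution, resolution), dtype=bool)
        rr, cc = _draw_polygon(v[:, 1], v[:, 0], shape=m.shape)
        m[rr, cc] = True
        return m

    count = np.logical_and(mask(a), mask(b)).sum()
    return float(count) / (scale * scale)
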