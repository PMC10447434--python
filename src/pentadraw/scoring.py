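"""Measure a pentagon drawing and rate it.

Three layers:

* :func:`extract_features` — blind raster measurement: find the closed
  figures, reconstruct each figure's region (splitting overlapping figures
  through the interior faces of the ink mask), count vertices by windowed
  turning-angle analysis of the region outline, and measure overlap,
  regularity, size, stroke width and edge straightness.
* :func:`conventional_rating` — the clinical pass/fail rule: two figures,
  five vertices each, and a present intersection.
* :func:`proxy_cognition_score` — a deterministic geometric stand-in for a
  learned image-to-cognition model: an additive-penalty score on the
  measured features, maximal for the ideal stimulus.  It is a documented
  surrogate for plugging into sweeps and cohort simulations, not a
  clinical instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.filters import threshold_otsu

from .simulator import RasterImage

__all__ = [
    "GeometricFeatures",
    "ConventionalRating",
    "NoFigureError",
    "extract_features",
    "conventional_rating",
    "proxy_cognition_score",
    "proxy_scorer",
    "PROXY_WEIGHTS",
]


class NoFigureError(ValueError):
    """Raised when an image contains no usable closed figure."""


@dataclass(frozen=True)
class GeometricFeatures:
    """Per-image measurements mirroring the simulator's attributes.

    ``overlap_fraction``, ``crossing_type`` and ``crossing_offset`` are
    undefined (None / "none") when fewer than two figures are found.
    """

    n_figures: int
    vertex_count_a: int
    vertex_count_b: int
    overlap_fraction: Optional[float]
    crossing_type: str  # none | vertex-vertex | vertex-side | other
    crossing_offset: Optional[float]  # mean vertex distance of crossings, edge units
    regularity_a: float
    regularity_b: float
    size_ratio: float
    figure_size: float
    stroke_width_px: float
    straightness: float
    vertices_a: np.ndarray = field(repr=False, default=None)
    vertices_b: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ConventionalRating:
    """Binary pass/fail with the list of violated criteria."""

    passed: int
    reasons: Tuple[str, ...]


# ---------------------------------------------------------------------------
# contour analysis


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed curve to n points uniform in arclength."""
    pts = points
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise NoFigureError("degenerate contour")
    ts = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(ts, s, closed[:, 0])
    y = np.interp(ts, s, closed[:, 1])
    return np.column_stack([x, y]), total


def _circular_gaussian_smooth(values: np.ndarray, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter1d(values, sigma, mode="wrap")


def _count_vertices(contour: np.ndarray, n_samples: int = 512,
                    smooth_frac: float = 0.02, window_frac: float = 0.08,
                    min_turn: float = 0.30,
                    rel_turn: float = 0.50) -> Tuple[int, np.ndarray, float]:
    """Count polygon vertices on a closed contour by windowed net turning.

    The contour is resampled uniformly, smoothed, and the tangent turning
    rate integrated over a sliding window of ``window_frac`` of the
    perimeter.  Corners show up as local maxima of net turning; wavy but
    straight-on-average edges integrate to ~0 and are ignored.  Returns
    (vertex count, vertex coordinates, perimeter).
    """
    (pts, _raw_perimeter) = _resample_closed(contour, n_samples)
    sigma = max(1.0, smooth_frac * n_samples)
    x = _circular_gaussian_smooth(pts[:, 0], sigma)
    y = _circular_gaussian_smooth(pts[:, 1], sigma)
    # Perimeter from a *lightly* smoothed copy: just enough to cancel the
    # half-pixel staircase of the raster contour without absorbing real
    # waviness (the corner-detection smoothing above is far heavier)
    sig_p = max(1.5, 0.004 * n_samples)
    xp = _circular_gaussian_smooth(pts[:, 0], sig_p)
    yp = _circular_gaussian_smooth(pts[:, 1], sig_p)
    sm = np.column_stack([xp, yp])
    perimeter = float(np.linalg.norm(np.diff(np.vstack([sm, sm[:1]]), axis=0),
                                     axis=1).sum())
    dx = np.gradient(x)
    dy = np.gradient(y)
    phi = np.arctan2(dy, dx)
    turn = np.diff(phi, append=phi[:1])
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    w = max(3, int(round(window_frac * n_samples)))
    kernel = np.ones(w)
    net = ndi.convolve1d(turn, kernel, mode="wrap")
    # Notches and nubs (tangent-contact artifacts, wave wiggles) carry
    # strong negative turning inside the same window; real convex corners
    # do not.  Exclude such candidates both from counting and from the
    # strongest-corner reference for the relative threshold.
    neg = ndi.convolve1d(np.minimum(turn, 0.0), kernel, mode="wrap")
    artifact = neg < -np.maximum(0.35, 0.5 * net)
    eligible = (net >= min_turn) & ~artifact
    if not eligible.any():
        return 0, np.empty((0, 2)), perimeter
    # local maxima above an absolute floor and a fraction of the strongest
    # valid corner, suppressing neighbours closer than ~60% of a window
    threshold = max(min_turn, rel_turn * float(net[eligible].max()))
    min_sep = max(3, int(round(0.06 * n_samples)))
    order = np.argsort(net)[::-1]
    taken: List[int] = []
    for idx in order:
        if net[idx] < threshold:
            break
        if not eligible[idx]:
            continue
        if all(_circ_dist(idx, j, n_samples) > min_sep for j in taken):
            taken.append(idx)
    if not taken:
        return 0, np.empty((0, 2)), perimeter
    taken.sort()
    # snap each corner from the smoothed curve (biased inward) to the raw
    # contour apex nearby: the point locally farthest from the centroid
    centroid = pts.mean(axis=0)
    radii = np.linalg.norm(pts - centroid, axis=1)
    verts = []
    for idx in taken:
        lo = idx - w // 2
        window_idx = np.arange(lo, lo + w) % n_samples
        apex = window_idx[np.argmax(radii[window_idx])]
        verts.append(pts[apex])
    return len(taken), np.array(verts), perimeter


def _circ_dist(i: int, j: int, n: int) -> int:
    d = abs(i - j)
    return min(d, n - d)


def _region_outline(region: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of a boolean region, as (x, y) points."""
    contours = skmeasure.find_contours(region.astype(float), 0.5)
    if not contours:
        raise NoFigureError("region has no contour")
    contour = max(contours, key=len)
    return contour[:, ::-1]  # rows,cols -> x,y


# ---------------------------------------------------------------------------
# figure segmentation


def _ink_mask(img: RasterImage) -> np.ndarray:
    px = img.pixels
    inv = 255 - px
    if inv.max() == inv.min():
        raise NoFigureError("blank image: no ink found")
    try:
        thr = threshold_otsu(inv)
    except ValueError:
        thr = 127
    mask = inv > max(thr, 50)
    if not mask.any():
        raise NoFigureError("blank image: no ink found")
    return mask


def _estimate_stroke_width(ink: np.ndarray) -> float:
    skel, dist = skmorph.medial_axis(ink, return_distance=True)
    vals = dist[skel]
    if vals.size == 0:
        return 1.0
    return float(2.0 * np.median(vals))


def _split_figures(ink: np.ndarray, stroke_width: float
                   ) -> Tuple[List[np.ndarray], Optional[np.ndarray]]:
    """Reconstruct per-figure filled regions from the ink mask.

    Disjoint figures are separate ink components.  Overlapping figures form
    one component whose interior splits into faces; the faces holding the
    horizontally extreme interior pixels are the two figure cores, faces
    reachable from both cores across one stroke lie inside both outlines
    (overlap, joining both regions), and faces reachable from exactly one
    core are severed fragments of that figure alone.  Returns (figure
    regions sorted by area desc, overlap region or None).
    """
    lab, n_comp = ndi.label(ink, structure=np.ones((3, 3)))
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_comp + 1))
    keep = [i + 1 for i in range(n_comp) if sizes[i] >= 30]
    if not keep:
        raise NoFigureError("no ink component large enough to be a figure")

    r_close = max(2, int(round(stroke_width / 2 + 2)))
    figures: List[np.ndarray] = []
    overlap: Optional[np.ndarray] = None

    for ci in keep:
        comp = lab == ci
        filled = ndi.binary_fill_holes(comp)
        interior = filled & ~comp
        faces, n_faces = ndi.label(interior)
        face_sizes = ndi.sum_labels(np.ones_like(faces), faces,
                                    index=np.arange(1, n_faces + 1))
        good = [f + 1 for f in range(n_faces)
                if face_sizes[f] >= max(40, 4 * stroke_width**2)]
        if len(good) <= 1:
            # a single simple figure (or an unresolvable near-coincident pair)
            figures.append(filled)
            continue
        # The two figure cores hold the horizontally extreme interior
        # pixels (the stimulus is a side-by-side pair); every other face
        # lies inside both figures' outlines and is overlap, so it joins
        # both reconstructed regions.
        cols = {f: np.nonzero((faces == f).any(axis=0))[0] for f in good}
        core_left = min(good, key=lambda f: cols[f].min())
        core_right = max(good, key=lambda f: cols[f].max())
        if core_left == core_right:
            figures.append(filled)
            continue
        # Classify the remaining faces by stroke-crossing adjacency: a face
        # bordering BOTH cores (reachable across one stroke) lies inside
        # both outlines and is overlap; a face bordering exactly one core
        # is a severed fragment of that figure alone.
        masks = {f: faces == f for f in good}
        dil = {f: ndi.binary_dilation(masks[f], structure=np.ones((3, 3)),
                                      iterations=r_close)
               for f in good if f not in (core_left, core_right)}
        lens = np.zeros_like(ink)
        extra = {core_left: np.zeros_like(ink),
                 core_right: np.zeros_like(ink)}
        for f in good:
            if f in (core_left, core_right):
                continue
            near_l = (dil[f] & masks[core_left]).any()
            near_r = (dil[f] & masks[core_right]).any()
            if near_l and not near_r:
                extra[core_left] |= masks[f]
            elif near_r and not near_l:
                extra[core_right] |= masks[f]
            else:
                lens |= masks[f]
        figures.append(_close_region(
            masks[core_left] | extra[core_left] | lens, r_close))
        figures.append(_close_region(
            masks[core_right] | extra[core_right] | lens, r_close))
        if lens.any():
            overlap = _close_region(lens, r_close)

    figures.sort(key=lambda m: int(m.sum()), reverse=True)
    return figures, overlap


def _close_region(mask: np.ndarray, r: int) -> np.ndarray:
    closed = ndi.binary_closing(mask, structure=skmorph.disk(r),
                                border_value=0)
    return ndi.binary_fill_holes(closed | mask)


# ---------------------------------------------------------------------------
# feature extraction


def extract_features(img: RasterImage, *, smooth_frac: float = 0.02,
                     window_frac: float = 0.08) -> GeometricFeatures:
    """Measure a (denoised, standardized) drawing.

    Raises :class:`NoFigureError` on blank images.  With fewer than two
    figures the overlap and crossing fields are undefined.
    """
    ink = _ink_mask(img)
    stroke_width = _estimate_stroke_width(ink)
    if stroke_width > 6:
        # thick strokes swallow the interior faces; analyse the topology on
        # the 1px skeleton instead (the width estimate keeps the original)
        ink_topo = ndi.binary_dilation(skmorph.skeletonize(ink))
        topo_width = 3.0
    else:
        ink_topo, topo_width = ink, stroke_width
    figures, overlap_region = _split_figures(ink_topo, topo_width)
    n_figures = len(figures)
    half = int(round(topo_width / 2))

    # open away sliver spikes narrower than the stroke (near-tangent tip
    # contacts leave such spurious bumps on a region), then grow by half
    # the stroke so areas refer to stroke centerlines
    r_open = max(2, int(round(topo_width)))

    def _despike(f: np.ndarray) -> np.ndarray:
        opened = ndi.binary_opening(f, structure=skmorph.disk(r_open))
        # keep the original if opening destroys the figure (tiny drawings)
        return opened if opened.sum() >= 0.5 * f.sum() else f

    figures = [_despike(f) for f in figures]
    grown = [ndi.binary_dilation(f, iterations=max(1, half)) for f in figures[:2]]

    infos = []
    for region in grown:
        outline = _region_outline(region)
        n_v, verts, perim = _count_vertices(outline, smooth_frac=smooth_frac,
                                            window_frac=window_frac)
        area = float(region.sum())
        centroid = np.array(ndi.center_of_mass(region))[::-1]
        infos.append(dict(n_v=n_v, verts=verts, perim=perim, area=area,
                          centroid=centroid, outline=outline))
    # order figures left to right for reporting stability
    infos.sort(key=lambda d: d["centroid"][0])

    def _regularity(info) -> float:
        verts = info["verts"]
        if len(verts) < 3:
            return 1.0
        edges = np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1)
        return float(edges.std() / edges.mean()) if edges.mean() > 0 else 1.0

    def _straightness(info) -> float:
        verts = info["verts"]
        if len(verts) < 3:
            return 0.0
        chord = np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1).sum()
        return max(0.0, float(info["perim"] / chord - 1.0)) if chord > 0 else 0.0

    def _circumradius(info) -> float:
        verts = info["verts"] if len(info["verts"]) >= 3 else info["outline"]
        return float(np.linalg.norm(verts - info["centroid"], axis=1).mean())

    a = infos[0]
    b = infos[1] if len(infos) > 1 else None

    if b is not None:
        areas = sorted([a["area"], b["area"]])
        size_ratio = areas[0] / areas[1]
        fig_size = np.mean([_circumradius(a), _circumradius(b)])
        if overlap_region is not None and overlap_region.any():
            inter = float((grown[0] & grown[1]).sum())
            overlap_fraction = min(1.0, inter / areas[0])
        else:
            inter = float((grown[0] & grown[1]).sum()) if len(grown) > 1 else 0.0
            overlap_fraction = min(1.0, inter / areas[0]) if areas[0] else 0.0
        crossing_type, crossing_offset = _crossing_analysis(a, b, overlap_fraction)
    else:
        size_ratio = 1.0
        fig_size = _circumradius(a)
        overlap_fraction = None
        crossing_type, crossing_offset = "none", None

    reg_a = _regularity(a)
    reg_b = _regularity(b) if b is not None else reg_a
    straight = np.mean([_straightness(i) for i in infos[:2]])

    return GeometricFeatures(
        n_figures=n_figures,
        vertex_count_a=a["n_v"],
        vertex_count_b=b["n_v"] if b is not None else 0,
        overlap_fraction=overlap_fraction,
        crossing_type=crossing_type,
        crossing_offset=crossing_offset,
        regularity_a=reg_a,
        regularity_b=reg_b,
        size_ratio=float(size_ratio),
        figure_size=float(fig_size / (img.width / 2.0)),
        stroke_width_px=stroke_width,
        straightness=float(straight),
        vertices_a=a["verts"],
        vertices_b=b["verts"] if b is not None else np.empty((0, 2)),
    )


def _crossing_analysis(a, b, overlap_fraction) -> Tuple[str, Optional[float]]:
    """Classify how the two figures cross, from boundary intersections.

    For each boundary crossing point we measure its distance to the
    nearest vertex of each figure (in mean-edge-length units) and report
    the mean *asymmetry* |d_a - d_b| as ``crossing_offset``.  A symmetric
    vertex-facing configuration crosses at points equidistant from both
    figures' nearest vertices (offset ~ 0); a vertex piercing the other
    figure's side puts crossings right next to one figure's vertex but
    mid-edge on the other (large offset).
    """
    from shapely.geometry import LinearRing

    if overlap_fraction is None or overlap_fraction <= 0:
        return "none", None
    va, vb = a["verts"], b["verts"]
    if len(va) < 3 or len(vb) < 3:
        return "other", None
    try:
        inter = LinearRing(va).intersection(LinearRing(vb))
    except Exception:
        return "other", None
    if inter.is_empty:
        return "other", None
    if inter.geom_type == "Point":
        pts = [(inter.x, inter.y)]
    else:
        pts = [(g.x, g.y) for g in getattr(inter, "geoms", [])
               if g.geom_type == "Point"]
    if not pts:
        return "other", None
    edge = 0.5 * (np.mean(np.linalg.norm(np.roll(va, -1, 0) - va, axis=1)) +
                  np.mean(np.linalg.norm(np.roll(vb, -1, 0) - vb, axis=1)))
    asyms = []
    for (x, y) in pts:
        p = np.array([x, y])
        da = float(np.linalg.norm(va - p, axis=1).min()) / edge
        db = float(np.linalg.norm(vb - p, axis=1).min()) / edge
        asyms.append(abs(da - db))
    offset = float(np.mean(asyms))
    if offset < 0.12:
        kind = "vertex-vertex"
    elif offset > 0.22:
        kind = "vertex-side"
    else:
        kind = "other"
    return kind, offset


# ---------------------------------------------------------------------------
# ratings


def conventional_rating(f: GeometricFeatures) -> ConventionalRating:
    """The clinical pass/fail rule for the pentagon item.

    Pass requires exactly two figures, five vertices on each, and a
    present intersection.
    """
    reasons: List[str] = []
    if f.n_figures != 2:
        reasons.append(f"figure count {f.n_figures} != 2")
    if f.vertex_count_a != 5 or f.vertex_count_b != 5:
        reasons.append("vertex count")
    if f.overlap_fraction is None or f.overlap_fraction <= 0:
        reasons.append("no intersection")
    return ConventionalRating(passed=int(not reasons), reasons=tuple(reasons))


# Penalty weights of the geometric proxy scorer, frozen here.  The scale is
# an arbitrary cognition z-like scale with ceiling PROXY_WEIGHTS["c0"].
PROXY_WEIGHTS: Dict[str, float] = {
    "c0": 1.0,             # ceiling score of a flawless drawing
    "vertex": 0.22,        # per unit |count - 5|, each figure
    "no_intersection": 1.2,
    "overlap": 0.8,        # x ((overlap - target)/(1 - target))^2
    "overlap_target": 0.07,  # overlap fraction of the canonical stimulus
    "overlap_floor": 0.03,   # the no-intersection penalty ramps in below this
    "crossing": 0.8,       # x crossing_offset (edge-length units)
    "regularity": 0.9,     # x (CV_a + CV_b)
    "size_equality": 0.6,  # x (1 - area ratio)
    "size": 2.0,           # x hinge((s_t - size)/s_t)^2 below s_t
    "size_threshold": 0.22,
    "line_width": 0.5,     # x hinge((w_t - width)/w_t) below w_t
    "width_threshold": 2.6,
    "waviness": 14.0,      # x straightness (path/chord - 1) above the floor
    "straightness_floor": 0.010,  # rasterization noise floor of straightness
}


def proxy_cognition_score(f: GeometricFeatures,
                          weights: Optional[Dict[str, float]] = None) -> float:
    """Deterministic additive-penalty cognition surrogate.

    Maximal at the ideal stimulus; each measured deviation subtracts a
    penalty: U-shaped in vertex count about 5, unimodal in overlap about a
    moderate target, monotone in irregularity / waviness / crossing
    offset, hinged at small sizes and very thin strokes.  Mirror-symmetric
    features make the score invariant to image flips.
    """
    w = dict(PROXY_WEIGHTS)
    if weights:
        w.update(weights)
    score = w["c0"]
    score -= w["vertex"] * (min(abs(f.vertex_count_a - 5), 5)
                            + min(abs(f.vertex_count_b - 5), 5))
    if f.overlap_fraction is None or f.overlap_fraction <= 0:
        score -= w["no_intersection"]
    else:
        t = w["overlap_target"]
        score -= w["overlap"] * ((f.overlap_fraction - t) / (1 - t)) ** 2
        # near-tangent drawings approach the no-intersection penalty
        # continuously instead of falling off a cliff at overlap == 0
        floor = w["overlap_floor"]
        short = max(0.0, (floor - f.overlap_fraction) / floor)
        score -= w["no_intersection"] * short ** 2
        if f.crossing_offset is not None:
            score -= w["crossing"] * f.crossing_offset
    score -= w["regularity"] * (f.regularity_a + f.regularity_b)
    score -= w["size_equality"] * (1.0 - f.size_ratio)
    st = w["size_threshold"]
    score -= w["size"] * max(0.0, (st - f.figure_size) / st) ** 2
    wt = w["width_threshold"]
    score -= w["line_width"] * max(0.0, (wt - f.stroke_width_px) / wt)
    score -= w["waviness"] * max(0.0, f.straightness - w["straightness_floor"])
    return float(score)


def proxy_scorer(img: RasterImage,
                 weights: Optional[Dict[str, float]] = None) -> float:
    """Image-to-score convenience: measure then score.

    Images in which no figure at all can be found receive the score of a
    maximally penalized drawing rather than raising, so batch sweeps stay
    alive on degenerate inputs.
    """
    w = dict(PROXY_WEIGHTS)
    if weights:
        w.update(weights)
    try:
        f = extract_features(img)
    except NoFigureError:
        return float(w["c0"] - w["no_intersection"] - 10 * w["vertex"]
                     - w["size"])
    return proxy_cognition_score(f, weights)


def features_from_geometry(truth, strokes=None,
                           canvas_width: int = 500) -> GeometricFeatures:
    """Exact features from the vector ground truth (no rasterization).

    The fast counterpart of :func:`extract_features` for simulator-linked
    cohorts: vertex counts, overlap, regularity and crossing geometry come
    from the exact polygons; straightness from the vector strokes when
    given, else from the spec's waviness via the arclength of a reference
    wavy path.
    """
    from .geometry import polygon_area, polygon_intersection_area

    pa, pb = truth.polygon_a, truth.polygon_b
    area_a, area_b = polygon_area(pa), polygon_area(pb)
    small, big = sorted([area_a, area_b])
    overlap = truth.overlap_fraction if truth.overlap_fraction > 0 else None

    def _cv(poly) -> float:
        e = poly.edge_lengths()
        return float(e.std() / e.mean())

    info_a = {"verts": pa.vertices}
    info_b = {"verts": pb.vertices}
    kind, offset = _crossing_analysis(info_a, info_b, overlap)

    if strokes is not None:
        straight = 0.0
        for poly, stroke in zip((pa, pb), strokes):
            arc = float(np.linalg.norm(np.diff(stroke, axis=0), axis=1).sum())
            chord = float(poly.edge_lengths().sum())
            straight += max(0.0, arc / chord - 1.0) / 2.0
    else:
        straight = 0.0

    radius = 0.5 * (
        float(np.linalg.norm(pa.vertices - pa.centroid, axis=1).mean()) +
        float(np.linalg.norm(pb.vertices - pb.centroid, axis=1).mean()))
    return GeometricFeatures(
        n_figures=2,
        vertex_count_a=pa.n,
        vertex_count_b=pb.n,
        overlap_fraction=truth.overlap_fraction,
        crossing_type=kind if overlap else "none",
        crossing_offset=offset,
        regularity_a=_cv(pa),
        regularity_b=_cv(pb),
        size_ratio=float(small / big),
        figure_size=float(radius / (canvas_width / 2.0)),
        stroke_width_px=float(truth.spec.line_width) + 1.0,  # AA bias of renders
        straightness=float(straight),
        vertices_a=pa.vertices,
        vertices_b=pb.vertices,
    )
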