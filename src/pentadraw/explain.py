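"""Attribute-sweep explainability for image-to-score functions.

The harness renders controlled image sets in which one drawing attribute
takes eight levels while all others jitter in a small window around the
ideal drawing, feeds every image to a scorer, and summarizes each level by
the median and the (unscaled) median absolute deviation of its replicate
scores.  Shape reports turn the per-level medians into machine-readable
statements — monotone, unimodal, argmax — that can be compared against
the qualitative behaviour expected of a cognition-score model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .imaging import AugmentConfig, tta_score
from .simulator import (
    DEFAULT_SWEEP_LEVELS,
    SWEEP_ATTRIBUTES,
    JitterConfig,
    RasterImage,
    canonical_attribute,
    child_seed,
    sweep_images,
)

__all__ = ["SweepResult", "run_sweep", "summarize_shape", "plot_sweep",
           "mean_ensemble"]


@dataclass(frozen=True)
class SweepResult:
    """Per-level replicate scores for one attribute sweep."""

    attribute: str
    levels: Tuple[float, ...]
    scores: Tuple[Tuple[float, ...], ...]  # one tuple of replicates per level
    scorer_id: str = "scorer"

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.scores):
            raise ValueError("one score tuple required per level")
        if any(len(s) == 0 for s in self.scores):
            raise ValueError("every level needs at least one replicate score")

    @property
    def medians(self) -> np.ndarray:
        return np.array([np.median(s) for s in self.scores])

    @property
    def mads(self) -> np.ndarray:
        """Unscaled median absolute deviation per level."""
        return np.array([np.median(np.abs(np.asarray(s) - np.median(s)))
                         for s in self.scores])


def mean_ensemble(*scorers: Callable[[RasterImage], float]
                  ) -> Callable[[RasterImage], float]:
    """Combine scorers into one by averaging their outputs per image."""
    if not scorers:
        raise ValueError("need at least one scorer")

    def _combined(img: RasterImage) -> float:
        return float(np.mean([s(img) for s in scorers]))

    return _combined


def run_sweep(
    scorer: Callable[[RasterImage], float],
    attribute: str,
    levels: Optional[Sequence[float]] = None,
    jitter: Optional[JitterConfig] = None,
    seed: int = 0,
    use_tta: bool = False,
    tta_variants: int = 30,
    scorer_id: str = "scorer",
) -> SweepResult:
    """Score a full 8-level sweep of one attribute.

    ``use_tta`` averages the scorer over augmented variants of each image
    (as a deployed model would be applied); the default scores the clean
    render once.  Deterministic given ``seed``.
    """
    attribute = canonical_attribute(attribute)
    images = sweep_images(attribute, levels, jitter, base_seed=seed)
    jitter = jitter or JitterConfig()
    reps = jitter.replicates
    level_values: List[float] = []
    per_level: List[List[float]] = []
    for i, (level, img, truth) in enumerate(images):
        if i % reps == 0:
            level_values.append(level)
            per_level.append([])
        try:
            if use_tta:
                rng = np.random.default_rng(child_seed(seed, "tta", i))
                val = tta_score(scorer, img, n_variants=tta_variants, rng=rng)
            else:
                val = float(scorer(img))
        except Exception as exc:
            li, ri = divmod(i, reps)
            raise RuntimeError(
                f"scorer failed at level {li} replicate {ri}: {exc}"
            ) from exc
        per_level[-1].append(val)
    return SweepResult(
        attribute=attribute,
        levels=tuple(level_values),
        scores=tuple(tuple(s) for s in per_level),
        scorer_id=scorer_id,
    )


def summarize_shape(r: SweepResult, tie_frac: float = 0.01,
                    mad_floor: float = 1.0) -> Dict[str, object]:
    """Machine-readable reading of a sweep's median curve.

    Ties are judged at the replicate noise floor: a difference between two
    adjacent level medians counts only if it exceeds both ``tie_frac`` of
    the overall median range and ``mad_floor`` times the larger of the two
    levels' MADs (the dispersion actually underlying those two medians).
    Unimodal means a single interior run of maxima with no second rise.
    """
    med = r.medians
    mads = r.mads
    rng_ = float(med.max() - med.min())
    base = tie_frac * rng_ if rng_ > 0 else 0.0
    diffs = np.diff(med)
    tols = np.array([max(base, mad_floor * max(mads[i], mads[i + 1]))
                     for i in range(len(med) - 1)])
    non_increasing = bool(np.all(diffs <= tols))
    non_decreasing = bool(np.all(diffs >= -tols))
    argmax = int(np.argmax(med))
    # unimodal: increases (within tol) up to the peak, decreases afterwards
    up = np.all(diffs[:argmax] >= -tols[:argmax]) if argmax > 0 else True
    down = (np.all(diffs[argmax:] <= tols[argmax:])
            if argmax < len(med) - 1 else True)
    return {
        "attribute": r.attribute,
        "argmax_level_index": argmax,
        "argmax_level": float(r.levels[argmax]),
        "monotone_non_increasing": non_increasing,
        "monotone_non_decreasing": non_decreasing,
        "unimodal": bool(up and down),
        "medians": [float(m) for m in med],
        "mads": [float(m) for m in r.mads],
        "levels": [float(l) for l in r.levels],
    }


def plot_sweep(results: SweepResult | Sequence[SweepResult], out: str) -> str:
    """Median +/- MAD per level, one panel per attribute; writes a figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(results, SweepResult):
        results = [results]
    results = list(results)
    if not results:
        raise ValueError("no sweep results to plot")
    n = len(results)
    ncols = min(4, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.2 * nrows),
                             squeeze=False)
    for ax in axes.flat[n:]:
        ax.axis("off")
    for ax, r in zip(axes.flat, results):
        ax.errorbar(r.levels, r.medians, yerr=r.mads, fmt="o-", capsize=3)
        ax.set_xlabel(r.attribute.replace("_", " "))
        ax.set_ylabel("predicted score")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
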