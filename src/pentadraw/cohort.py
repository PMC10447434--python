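"""Synthetic aging-cohort generator for the evaluation layer.

Emulates the structure of a longitudinal memory-and-aging study: each
participant has a latent cognition trajectory declining with age, yearly
visits with a global cognition composite (z-scaled), 30 binary MMSE items
generated from the latent level through item thresholds, a clinical
diagnosis (NCI / MCI / DM) from a noisy read of the latent level, and a
pentagon drawing per visit whose attributes (waviness, angular distortion,
size, placement, vertex slips) drift with impairment.  The drawing is
scored by the geometric proxy model — by default on the exact vector
geometry (fast), optionally by rendering and measuring the raster — and
rated pass/fail by the conventional rule.

This is a synthetic stand-in for restricted clinical cohort data: it
reproduces directions of effect and data shapes, not population values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import IDEAL_SPEC, PentagonSpec
from .scoring import (
    conventional_rating,
    extract_features,
    features_from_geometry,
    proxy_cognition_score,
)
from .simulator import build_drawing, child_seed, generate
from .stats import mmse_item_columns

__all__ = ["EffectConfig", "generate_cohort"]


@dataclass(frozen=True)
class EffectConfig:
    """How strongly impairment (negative latent cognition) moves drawing
    attributes, per unit of impairment.

    Waviness carries the strongest effect, matching its role as the most
    influential drawing attribute; ``score_noise`` is the SD of the
    residual added to the proxy score (model error), ``rating_flip`` the
    probability that the binary rating is misrecorded (rater error).
    """

    waviness: float = 0.030
    distortion: float = 0.050
    size: float = 0.040
    distance_sd: float = 0.060  # placement variability added per impairment
    vertex_slip: float = 0.15   # added P(wrong vertex count) per impairment
    score_noise: float = 0.15
    rating_flip: float = 0.02

    @classmethod
    def zero(cls) -> "EffectConfig":
        return cls(waviness=0.0, distortion=0.0, size=0.0, distance_sd=0.0,
                   vertex_slip=0.0, score_noise=0.15, rating_flip=0.02)


def _spec_for_visit(latent: float, cfg: EffectConfig,
                    rng: np.random.Generator, seed: int) -> PentagonSpec:
    impair = max(0.0, -latent)
    waviness = float(np.clip(0.008 + cfg.waviness * impair
                             + rng.normal(0, 0.004), 0.0, 0.2))
    distortion = float(np.clip(0.02 + cfg.distortion * impair
                               + abs(rng.normal(0, 0.01)), 0.0, 0.5))
    size = float(np.clip(0.35 - cfg.size * impair + rng.normal(0, 0.02),
                         0.08, 0.5))
    distance = float(np.clip(
        0.75 + rng.normal(0, 0.04 + cfg.distance_sd * impair), 0.05, 1.45))
    alignment = float(rng.uniform(0, 1))
    size_eq = float(np.clip(1.0 + rng.normal(0, 0.06 + 0.04 * impair),
                            0.4, 1.8))

    def _vertices() -> int:
        p_wrong = min(0.6, 0.03 + cfg.vertex_slip * impair)
        if rng.uniform() < p_wrong:
            return int(np.clip(5 + rng.choice([-2, -1, 1, 2]), 3, 10))
        return 5

    return IDEAL_SPEC.with_(
        n_vertices_a=_vertices(),
        n_vertices_b=_vertices(),
        distance=distance,
        alignment=alignment,
        angle_distortion=distortion,
        size_equality=size_eq,
        size=size,
        waviness=waviness,
        seed=seed,
    )


def generate_cohort(
    n_participants: int = 500,
    visits_per_participant: int = 3,
    effect_config: Optional[EffectConfig] = None,
    seed: int = 0,
    render: bool = False,
    return_specs: bool = False,
) -> pd.DataFrame | Tuple[pd.DataFrame, List[PentagonSpec]]:
    """Simulate a per-visit cohort table.

    ``render=False`` (default) scores the drawing from its exact vector
    geometry; ``render=True`` rasterizes each drawing and scores the
    measured features, which is slower but exercises the full pipeline.
    Fully deterministic given ``seed``.
    """
    if n_participants < 1 or visits_per_participant < 1:
        raise ValueError("cohort sizes must be positive")
    cfg = effect_config or EffectConfig()
    for name in ("waviness", "distortion", "size", "distance_sd",
                 "vertex_slip", "score_noise", "rating_flip"):
        if getattr(cfg, name) < 0:
            raise ValueError(f"effect_config.{name} must be >= 0")
    rng = np.random.default_rng(seed)
    rows: List[Dict[str, object]] = []
    specs: List[PentagonSpec] = []
    item_cols = mmse_item_columns()
    # item difficulties: most items easy for this population, a few hard
    difficulties = np.sort(rng.normal(-2.0, 0.9, size=29))

    for pid in range(n_participants):
        age0 = rng.normal(77.4, 7.0)
        education = float(np.clip(rng.normal(15.9, 3.0), 6, 25))
        latent0 = rng.normal(0.0, 1.0) - 0.03 * (age0 - 77.4)
        slope = max(0.0, rng.normal(0.10, 0.06))
        for visit in range(visits_per_participant):
            latent = latent0 - slope * visit + rng.normal(0, 0.10)
            global_cog = latent + rng.normal(0, 0.30)

            spec_seed = child_seed(seed, "spec", pid, visit)
            spec = _spec_for_visit(latent, cfg, rng, spec_seed)
            if render:
                img, truth = generate(spec)
                feats = extract_features(img)
            else:
                drawing, truth = build_drawing(spec)
                feats = features_from_geometry(truth, drawing.strokes)
            score = proxy_cognition_score(feats) + rng.normal(
                0, cfg.score_noise)
            rating = conventional_rating(feats).passed
            if rng.uniform() < cfg.rating_flip:
                rating = 1 - rating

            # diagnosis from a noisy clinical read of the latent level
            clin = latent + rng.normal(0, 0.35)
            if clin > -0.75:
                dx = "NCI"
            elif clin > -1.75:
                dx = "MCI"
            else:
                dx = "DM"

            p_items = 1.0 / (1.0 + np.exp(-1.3 * (latent - difficulties)))
            items = (rng.uniform(size=29) < p_items).astype(int)

            row: Dict[str, object] = {
                "participant_id": pid,
                "visit_index": visit,
                "drawing_score": float(score),
                "binary_rating": int(rating),
                "global_cognition": float(global_cog),
                "diagnosis": dx,
                "age": float(age0 + visit),
                "education": education,
                "fold": -1,
            }
            for col, val in zip(item_cols[:-1], items):
                row[col] = int(val)
            row[item_cols[-1]] = int(rating)  # pentagon item = conventional rating
            rows.append(row)
            specs.append(spec)

    table = pd.DataFrame(rows)
    if return_specs:
        return table, specs
    return table
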