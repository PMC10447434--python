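"""Evaluation statistics for drawing-derived cognition scores.

Person-grouped cross-validation and out-of-fold prediction (so no model is
evaluated on a participant it saw in training), hierarchical-partitioning
variance decomposition (LMG / Chevan–Sutherland: a predictor's importance
is its incremental R^2 averaged over all orders of entry), nonparametric
AUC with DeLong's test for correlated ROC curves, out-of-fold logistic
calibration of a continuous score into a 0-1 probability, and the
composition of that probability with MMSE totals.

Cohort tables are plain :class:`pandas.DataFrame` objects with the column
schema documented in :data:`COHORT_COLUMNS`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "COHORT_COLUMNS",
    "RelativeImportance",
    "assign_folds",
    "out_of_fold_predict",
    "variance_explained",
    "roc_auc",
    "delong_test",
    "calibrate_to_probability",
    "mmse_integrate",
    "diagnosis_contrast_table",
]

#: Core column schema of a cohort table.  ``mmse_item_01`` .. ``mmse_item_30``
#: are the binary item scores; item 30 is the pentagon-copy item.
COHORT_COLUMNS = (
    "participant_id",
    "visit_index",
    "drawing_score",
    "binary_rating",
    "global_cognition",
    "diagnosis",
    "age",
    "education",
    "fold",
)

PENTAGON_ITEM = "mmse_item_30"


def mmse_item_columns(include_pentagon: bool = True) -> List[str]:
    cols = [f"mmse_item_{i:02d}" for i in range(1, 31)]
    return cols if include_pentagon else cols[:-1]


# ---------------------------------------------------------------------------
# folds and out-of-fold prediction


def assign_folds(table: pd.DataFrame, k: int = 10,
                 seed: int = 0) -> pd.DataFrame:
    """Assign a person-grouped fold to every row.

    All visits of one participant share a fold; fold sizes are balanced by
    participant count within one.  Returns a copy with the ``fold`` column
    set.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    participants = table["participant_id"].unique()
    if len(participants) < k:
        raise ValueError(
            f"need at least k={k} participants, got {len(participants)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(participants))
    fold_of = {participants[p]: i % k for i, p in enumerate(order)}
    out = table.copy()
    out["fold"] = out["participant_id"].map(fold_of).astype(int)
    return out


def out_of_fold_predict(
    table: pd.DataFrame,
    fitter: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    k: int = 10,
    seed: int = 0,
) -> Tuple[np.ndarray, List[Callable]]:
    """Concatenated held-out predictions over person-grouped folds.

    ``fitter(train_rows)`` must return a function mapping a row table to
    predictions.  Every row is predicted exactly once, by a model whose
    training folds exclude that row's participant.  Returns the per-row
    prediction vector (aligned with ``table``) and the k fitted scorers.
    """
    if "fold" in table.columns and table["fold"].notna().all() and \
            table["fold"].nunique() >= 2:
        work = table
    else:
        work = assign_folds(table, k=k, seed=seed)
    folds = np.sort(work["fold"].unique())
    preds = np.full(len(work), np.nan)
    models: List[Callable] = []
    for f in folds:
        test_mask = (work["fold"] == f).to_numpy()
        train = work.loc[~test_mask]
        # leakage audit: no shared participants between train and test
        shared = set(train["participant_id"]) & set(
            work.loc[test_mask, "participant_id"])
        if shared:
            raise RuntimeError(f"participant leakage across fold {f}: {shared}")
        try:
            model = fitter(train)
        except Exception as exc:
            raise RuntimeError(f"fitter failed on fold {f}: {exc}") from exc
        preds[test_mask] = np.asarray(model(work.loc[test_mask]), dtype=float)
        models.append(model)
    if np.isnan(preds).any():
        raise RuntimeError("some rows received no out-of-fold prediction")
    return preds, models


# ---------------------------------------------------------------------------
# variance decomposition (LMG / hierarchical partitioning)


@dataclass(frozen=True)
class RelativeImportance:
    """Per-predictor share of explained variance; shares sum to full R^2."""

    predictors: Tuple[str, ...]
    shares: Tuple[float, ...]
    r_squared: float

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.predictors, self.shares))


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: Tuple[int, ...],
               cache: Dict[Tuple[int, ...], float]) -> float:
    if cols in cache:
        return cache[cols]
    if not cols:
        cache[cols] = 0.0
        return 0.0
    Z = np.column_stack([np.ones(len(y)), X[:, cols]])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
    cache[cols] = r2
    return r2


def variance_explained(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    names: Optional[Sequence[str]] = None,
) -> RelativeImportance:
    """LMG relative importance by exact enumeration over subsets.

    Each predictor's share is its incremental R^2 averaged over all p!
    orderings of predictor entry, computed from the 2^p subset R^2 values
    with the combinatorial ordering weights.  Limited to p <= 10 so the
    enumeration stays exact; shares are >= 0 (up to numerical noise) for
    OLS and sum to the full-model R^2.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p > 10:
        raise ValueError("exact enumeration limited to at most 10 predictors")
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        raise ValueError("rank-deficient predictor matrix")

    cache: Dict[Tuple[int, ...], float] = {}
    shares = np.zeros(p)
    idx = tuple(range(p))
    fact = [math.factorial(i) for i in range(p + 1)]
    for j in range(p):
        others = tuple(i for i in idx if i != j)
        for r in range(p):
            weight = fact[r] * fact[p - r - 1] / fact[p]
            for subset in itertools.combinations(others, r):
                base = tuple(sorted(subset))
                withj = tuple(sorted(subset + (j,)))
                shares[j] += weight * (_subset_r2(y, X, withj, cache)
                                       - _subset_r2(y, X, base, cache))
    full = _subset_r2(y, X, idx, cache)
    return RelativeImportance(
        predictors=tuple(names), shares=tuple(float(s) for s in shares),
        r_squared=float(full),
    )


# ---------------------------------------------------------------------------
# ROC / DeLong


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return (labels == classes.max()).astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney probability, ties counted half."""
    y = _check_labels(np.asarray(labels))
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels length mismatch")
    pos, neg = s[y == 1], s[y == 0]
    # midranks give the tie-corrected Mann-Whitney statistic
    ranks = sps.rankdata(s)
    auc = (ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg))
    return float(auc)


def _placements(scores: np.ndarray, y: np.ndarray
                ) -> Tuple[float, np.ndarray, np.ndarray]:
    """DeLong placement values via midranks."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-negative placements
    auc = v10.mean()
    return float(auc), v10, v01


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> Tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs on the same subjects.

    Returns (AUC_a, AUC_b, z, two-sided p).  The covariance of the paired
    AUC estimators comes from the empirical covariance of the placement
    values, so ties must use the same half-weight convention as
    :func:`roc_auc` (they do: both use midranks).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must have equal length")
    y = _check_labels(np.asarray(labels))
    if len(y) != len(sa):
        raise ValueError("scores and labels length mismatch")
    auc_a, v10a, v01a = _placements(sa, y)
    auc_b, v10b, v01b = _placements(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))  # 2x2, positives
    s01 = np.cov(np.vstack([v01a, v01b]))  # 2x2, negatives
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
          (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = diff / math.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


# ---------------------------------------------------------------------------
# calibration and MMSE integration


def calibrate_to_probability(
    score: Sequence[float],
    diagnosis_binary: Sequence[int],
    folds: Sequence[int],
    ridge: float = 0.0,
) -> np.ndarray:
    """Out-of-fold logistic calibration of a continuous score into [0, 1].

    Each row's probability comes from a logistic model fitted on the other
    folds only, keeping calibration strictly separated from application.
    ``ridge > 0`` adds an L2 penalty for separable small cohorts.
    """
    import statsmodels.api as sm

    s = np.asarray(score, dtype=float)
    yb = np.asarray(diagnosis_binary, dtype=int)
    f = np.asarray(folds)
    if not (len(s) == len(yb) == len(f)):
        raise ValueError("score, labels and folds must align")
    probs = np.full(len(s), np.nan)
    for fold in np.unique(f):
        test = f == fold
        ytr, str_ = yb[~test], s[~test]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"single-class training partition for fold {fold}")
        if np.ptp(str_) == 0:
            # constant score: intercept-only model, probability = prevalence
            probs[test] = ytr.mean()
            continue
        Xtr = sm.add_constant(str_)
        Xte = sm.add_constant(s[test], has_constant="add")
        try:
            if ridge > 0:
                model = sm.Logit(ytr, Xtr).fit_regularized(
                    alpha=ridge, L1_wt=0.0, disp=0)
            else:
                model = sm.Logit(ytr, Xtr).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise RuntimeError(
                f"logistic calibration failed on fold {fold}; "
                f"consider ridge > 0: {exc}"
            ) from exc
        probs[test] = model.predict(Xte)
    return probs


MMSE_MODES = ("MMSE29+score", "MMSE30+score", "MMSE29", "MMSE30")


def mmse_integrate(
    mmse_items: pd.DataFrame,
    probability: Optional[Sequence[float]] = None,
    mode: str = "MMSE29+score",
) -> np.ndarray:
    """Compose MMSE totals with a calibrated drawing probability.

    MMSE30 is the 30-item total; MMSE29 drops the pentagon-copy item.
    ``+score`` modes add the probability (in [0, 1]) to the base total, so
    MMSE29+score spans [0, 30] like the conventional MMSE30.
    """
    if mode not in MMSE_MODES:
        raise ValueError(f"mode must be one of {MMSE_MODES}")
    cols29 = mmse_item_columns(include_pentagon=False)
    missing = [c for c in cols29 if c not in mmse_items.columns]
    if missing:
        raise ValueError(f"missing MMSE item columns: {missing[:3]} ...")
    base29 = mmse_items[cols29].to_numpy(dtype=float).sum(axis=1)
    if mode.startswith("MMSE30"):
        if PENTAGON_ITEM not in mmse_items.columns:
            raise ValueError(f"mode {mode} requires the {PENTAGON_ITEM} column")
        base = base29 + mmse_items[PENTAGON_ITEM].to_numpy(dtype=float)
    else:
        base = base29
    if mode.endswith("+score"):
        if probability is None:
            raise ValueError(f"mode {mode} requires a probability vector")
        prob = np.asarray(probability, dtype=float)
        if np.any((prob < 0) | (prob > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        return base + prob
    return base


def diagnosis_contrast_table(table: pd.DataFrame, contrast: str
                             ) -> pd.DataFrame:
    """Rows for a two-group diagnosis contrast, e.g. ``"NCI-DM"``.

    Uses each participant's first visit at the target diagnosis for the
    impaired groups and the baseline visit for NCI, the convention for
    early-detection ROC contrasts.
    """
    try:
        g1, g2 = contrast.split("-")
    except ValueError as exc:
        raise ValueError("contrast must look like 'NCI-DM'") from exc
    # a participant reaching the more-impaired group belongs to it; the
    # less-impaired group keeps only participants who never reach g2
    sub2 = table[table["diagnosis"] == g2]
    impaired_ids = set(sub2["participant_id"])
    sub1 = table[(table["diagnosis"] == g1)
                 & ~table["participant_id"].isin(impaired_ids)]
    parts = []
    for g, sub in ((g1, sub1), (g2, sub2)):
        if sub.empty:
            raise ValueError(f"no rows with diagnosis {g!r}")
        # first visit carrying the group's diagnosis: the first diagnosed
        # visit for impaired groups, the baseline visit for NCI
        pick = sub.sort_values("visit_index").groupby(
            "participant_id", as_index=False).first()
        parts.append(pick)
    out = pd.concat(parts, ignore_index=True)
    out["label"] = (out["diagnosis"] == g2).astype(int)
    return out
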