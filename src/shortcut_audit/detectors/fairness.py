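"""Fairness-paradigm detectors.

These detectors audit the *behavior* of a small downstream task
classifier trained on the embeddings, rather than the embedding geometry
itself:

* ``demographic_parity`` — disparity in positive-prediction rates
  between attribute groups, measured in its strong form (the maximal
  positive-rate gap over all decision thresholds, i.e. the KS distance
  between the groups' held-out score distributions).  With the strict
  default tolerance this flags whenever the two score distributions are
  distinguishable at all — deliberately uncalibrated, reproducing the
  always-flag-on-null behavior the adjusted counts exclude.
* ``equalized_odds`` — max of TPR and FPR gaps between groups on
  held-out predictions, calibrated by a label-permutation test.
* ``intersectional`` — positive-rate gap of each attribute-intersection
  cell against its complement; applicable only with >= 2 attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from ..data import EmbeddingDataset
from ..errors import ValidationError
from ..results import DetectorResult
from .base import check_binary_attribute, standardize


@dataclass
class DownstreamModel:
    """Cross-validated linear task head Y ~ E with out-of-fold predictions."""

    kind: str
    folds: int
    labels: np.ndarray
    predictions: np.ndarray  # held-out hard labels
    scores: np.ndarray  # held-out decision scores
    seed: int
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy = float((self.predictions == self.labels).mean())


def fit_downstream(
    ds: EmbeddingDataset, seed: int = 0, folds: int = 5
) -> DownstreamModel:
    """Fit the downstream task classifier with stratified CV.

    Every sample receives exactly one held-out prediction; reproducible
    from ``seed``.
    """
    y = np.asarray(ds.task_labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("downstream model needs both task classes present")
    if counts.min() < folds:
        raise ValidationError(
            f"each task class needs >= folds={folds} samples "
            f"(smallest class has {counts.min()})"
        )
    X = standardize(ds.embeddings)
    cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    clf = LogisticRegression(max_iter=100, tol=1e-2, random_state=seed)
    scores = cross_val_predict(cv=cv, estimator=clf, X=X, y=y, method="decision_function")
    preds = (scores > 0).astype(np.int64)
    return DownstreamModel(
        kind="linear", folds=folds, labels=y.astype(np.int64),
        predictions=preds, scores=np.asarray(scores, float), seed=seed,
    )


def _max_threshold_gap(scores: np.ndarray, a: np.ndarray) -> float:
    """Strong demographic-parity gap: sup over thresholds t of
    |P(score > t | A=0) - P(score > t | A=1)| (the KS distance between
    the two score distributions)."""
    s0 = np.sort(scores[a == 0])
    s1 = np.sort(scores[a == 1])
    grid = np.concatenate([s0, s1])
    cdf0 = np.searchsorted(s0, grid, side="right") / s0.size
    cdf1 = np.searchsorted(s1, grid, side="right") / s1.size
    return float(np.abs(cdf0 - cdf1).max())


def detect_demographic_parity(
    model: DownstreamModel,
    ds: EmbeddingDataset,
    attr: str,
    epsilon: float = 0.01,
) -> DetectorResult:
    """Strict strong-parity check of held-out task predictions across A."""
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("demographic_parity", str(e))
    if (a == 0).sum() == 0 or (a == 1).sum() == 0:
        return DetectorResult.not_applicable("demographic_parity", "empty group")
    gap = _max_threshold_gap(model.scores, a)
    rate0 = float(model.predictions[a == 0].mean())
    rate1 = float(model.predictions[a == 1].mean())
    score = float(np.clip(gap / 0.2, 0.0, 1.0))
    threshold = float(np.clip(epsilon / 0.2 - 1e-12, 0.0, 1.0))
    return DetectorResult(
        method_name="demographic_parity",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        details={
            "gap": gap,
            "gap_definition": "max positive-rate gap over decision thresholds",
            "hard_label_gap": abs(rate0 - rate1),
            "positive_rate_a0": rate0,
            "positive_rate_a1": rate1,
            "epsilon": epsilon,
        },
    )


def _eo_gap(y: np.ndarray, yhat: np.ndarray, a: np.ndarray) -> float:
    gaps = []
    for yval in (1, 0):  # TPR gap then FPR gap
        m = y == yval
        r0 = yhat[m & (a == 0)].mean()
        r1 = yhat[m & (a == 1)].mean()
        gaps.append(abs(r0 - r1))
    return float(max(gaps))


def detect_equalized_odds(
    model: DownstreamModel,
    ds: EmbeddingDataset,
    attr: str,
    gap_threshold: float = 0.10,
    permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> DetectorResult:
    """Equalized-odds gap with a permutation-calibrated flag.

    Flags only when the gap is both large (> ``gap_threshold``) and
    unlikely under random attribute assignment (permutation p <= alpha),
    so sampling noise alone does not fire it.
    """
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("equalized_odds", str(e))
    y, yhat = model.labels, model.predictions
    for yv in (0, 1):
        for av in (0, 1):
            if ((y == yv) & (a == av)).sum() == 0:
                return DetectorResult.not_applicable(
                    "equalized_odds", f"empty (Y={yv}, A={av}) cell"
                )
    gap = _eo_gap(y, yhat, a)
    rng = np.random.default_rng(seed)
    null = np.array(
        [_eo_gap(y, yhat, rng.permutation(a)) for _ in range(permutations)]
    )
    p = float((1 + (null >= gap).sum()) / (1 + permutations))
    null_cut = float(np.quantile(null, 1.0 - alpha))
    score = float(np.clip(gap / 0.4, 0.0, 1.0))
    threshold = float(np.clip(max(gap_threshold, null_cut) / 0.4, 0.0, 1.0))
    return DetectorResult(
        method_name="equalized_odds",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        details={
            "gap": gap,
            "permutation_p": p,
            "null_95th": null_cut,
            "gap_threshold": gap_threshold,
            "permutations": permutations,
            "seed": seed,
        },
    )


def detect_intersectional(
    model: DownstreamModel,
    ds: EmbeddingDataset,
    attrs: list[str],
    epsilon: float = 0.01,
    min_cell: int = 20,
) -> DetectorResult:
    """Intersectional positive-rate disparities across >= 2 attributes.

    Each sufficiently large intersection cell is compared against its
    complement; the detector flags only when some intersectional gap
    exceeds both the tolerance and the largest single-attribute gap
    (i.e. the intersection adds information beyond marginal disparity).
    """
    if len(attrs) < 2:
        return DetectorResult.not_applicable(
            "intersectional", "requires at least two sensitive attributes"
        )
    try:
        mats = [check_binary_attribute(ds, name) for name in attrs]
    except ValidationError as e:
        return DetectorResult.not_applicable("intersectional", str(e))
    yhat = model.predictions

    single_gaps = {}
    for name, a in zip(attrs, mats):
        if (a == 0).sum() == 0 or (a == 1).sum() == 0:
            return DetectorResult.not_applicable(
                "intersectional", f"attribute {name!r} has an empty group"
            )
        single_gaps[name] = abs(
            float(yhat[a == 0].mean()) - float(yhat[a == 1].mean())
        )
    max_single = max(single_gaps.values())

    stacked = np.stack(mats, axis=1)
    cells, inverse = np.unique(stacked, axis=0, return_inverse=True)
    max_gap = 0.0
    cell_stats = []
    merged_out = 0
    for ci in range(len(cells)):
        mask = inverse == ci
        if mask.sum() < min_cell:
            merged_out += 1
            continue
        gap = abs(float(yhat[mask].mean()) - float(yhat[~mask].mean()))
        cell_stats.append(
            {
                "cell": {a: int(v) for a, v in zip(attrs, cells[ci])},
                "size": int(mask.sum()),
                "gap": gap,
            }
        )
        max_gap = max(max_gap, gap)
    if not cell_stats:
        return DetectorResult.not_applicable(
            "intersectional", f"no intersection cell has >= {min_cell} samples"
        )
    score = float(np.clip(max_gap / 0.2, 0.0, 1.0))
    threshold = float(np.clip(max(epsilon, max_single) / 0.2, 0.0, 1.0))
    return DetectorResult(
        method_name="intersectional",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        details={
            "max_intersectional_gap": max_gap,
            "single_attribute_gaps": single_gaps,
            "cells": cell_stats,
            "cells_merged_out": merged_out,
            "epsilon": epsilon,
            "min_cell": min_cell,
        },
    )
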