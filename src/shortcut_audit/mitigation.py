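"""Embedding-level mitigation transforms and the pre/post re-audit loop.

All transforms preserve the sample count and order; the re-audit reruns
the identical detection pipeline (same methods, settings and seeds) on
the transformed embeddings, so pre/post agreement counts are directly
comparable.  Task utility (held-out downstream accuracy) is reported on
both sides because attribute removal can cost predictive signal.

A warning worth keeping in mind: projecting out a single bias direction
removes rank-1 mean structure only.  When the attribute is encoded with
higher rank (several shift magnitudes, variance differences), cluster-
based detectors may legitimately keep flagging after erasure — the loop
asserts nothing beyond what it reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .audit import run_audit
from .data import EmbeddingDataset
from .detectors.base import check_binary_attribute, standardize
from .detectors.fairness import DownstreamModel, fit_downstream
from .errors import ValidationError
from .results import AuditReport

log = logging.getLogger("shortcut_audit")

MITIGATION_METHODS = (
    "dimension_masking",
    "bias_direction_erasure",
    "adversarial_debias",
    "last_layer_retraining",
    "contrastive_debias",
)


def mask_dimensions(
    ds: EmbeddingDataset, dims: Sequence[int] | frozenset[int]
) -> EmbeddingDataset:
    """Replace the listed dimensions by their pooled mean (information-free)."""
    dims = sorted({int(i) for i in dims})
    if any(i < 0 or i >= ds.d for i in dims):
        raise ValidationError(f"mask dims out of range [0, {ds.d}): {dims}")
    E = ds.embeddings.copy()
    if dims:
        E[:, dims] = E[:, dims].mean(axis=0)
    return ds.replace_embeddings(E)


def erase_bias_direction(
    ds: EmbeddingDataset, attr: str, rounds: int = 3
) -> EmbeddingDataset:
    """Iterative projection onto the orthogonal complement of the group
    centroid-difference direction (recomputed each round)."""
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    a = check_binary_attribute(ds, attr)
    E = ds.embeddings.copy()
    for r in range(rounds):
        w = E[a == 1].mean(axis=0) - E[a == 0].mean(axis=0)
        norm = np.linalg.norm(w)
        if norm <= 1e-12:
            log.warning("erase_bias_direction: degenerate direction at round %d", r)
            break
        w = w / norm
        E = E - np.outer(E @ w, w)
    return ds.replace_embeddings(E)


def adversarial_debias(
    ds: EmbeddingDataset,
    attr: str,
    lam: float = 1.0,
    epochs: int = 100,
    learning_rate: float = 0.05,
    adversary_steps: int = 5,
    adversary_lr: float = 1.0,
    seed: int = 0,
) -> EmbeddingDataset:
    """Learn a linear map of the embeddings that keeps the task label
    predictable while an adversary head predicting A is suppressed.

    Each epoch: the task head descends its CE; the adversary head takes
    a few inner CE steps; the map then descends the task loss while the
    adversarial term shrinks the group-mean separation along the
    adversary's current direction (the statistic the adversary exploits
    — ascending the adversary's CE directly has a vanishing gradient
    once the adversary converges).  Deterministic given ``seed``.
    """
    a = check_binary_attribute(ds, attr).astype(float)
    y = np.asarray(ds.task_labels, dtype=float)
    X = standardize(ds.embeddings)
    n, d = X.shape
    dmu_x = X[a == 1].mean(axis=0) - X[a == 0].mean(axis=0)
    M = np.eye(d)
    u = np.zeros(d)
    bu = 0.0
    v = np.zeros(d)
    bv = 0.0

    def sig(z: np.ndarray) -> np.ndarray:
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    for _ in range(epochs):
        Z = X @ M
        # task head step (minimize task CE)
        gt = (sig(Z @ u + bu) - y) / n
        u -= learning_rate * (Z.T @ gt)
        bu -= learning_rate * gt.sum()
        # adversary head: a few inner CE steps so it tracks the residual
        # attribute direction
        for _ in range(adversary_steps):
            ga = (sig(Z @ v + bv) - a) / n
            v -= adversary_lr * (Z.T @ ga)
            bv -= adversary_lr * ga.sum()
        nv = np.linalg.norm(v)
        vn = v / nv if nv > 0 else v
        sep = float((Z[a == 1].mean(axis=0) - Z[a == 0].mean(axis=0)) @ vn)
        # map step: task descent + reversal on the separation statistic
        gt = (sig(Z @ u + bu) - y) / n
        gM = np.outer(X.T @ gt, u) + lam * 2.0 * sep * np.outer(dmu_x, vn)
        M -= learning_rate * gM
        if not np.isfinite(M).all():
            raise ValidationError(
                "adversarial_debias diverged (non-finite map); "
                f"lam={lam}, lr={learning_rate}"
            )
    return ds.replace_embeddings(X @ M)


def last_layer_retrain(
    ds: EmbeddingDataset, attr: str, seed: int = 0
) -> DownstreamModel | None:
    """Retrain the downstream task head on a group-balanced subsample.

    Changes the head, not the embeddings: equal counts are drawn from
    every (Y, A) cell, the linear head is refit, and its held-out
    predictions over the full data are returned for fairness
    re-evaluation.  Returns None (not applicable) when a cell is empty
    or below 10 samples.
    """
    a = check_binary_attribute(ds, attr)
    y = np.asarray(ds.task_labels, dtype=np.int64)
    cells = {}
    for yv in np.unique(y):
        for av in (0, 1):
            idx = np.flatnonzero((y == yv) & (a == av))
            if idx.size < 10:
                log.warning(
                    "last_layer_retrain: cell (Y=%s, A=%s) has %d < 10 samples",
                    yv, av, idx.size,
                )
                return None
            cells[(int(yv), av)] = idx
    m = min(idx.size for idx in cells.values())
    rng = np.random.default_rng(seed)
    take = np.concatenate(
        [rng.choice(idx, size=m, replace=False) for idx in cells.values()]
    )
    X = standardize(ds.embeddings)
    clf = LogisticRegression(max_iter=200, random_state=seed)
    clf.fit(X[take], y[take])
    scores = clf.decision_function(X)
    preds = (scores > 0).astype(np.int64)
    return DownstreamModel(
        kind="linear", folds=1, labels=y, predictions=preds,
        scores=np.asarray(scores, float), seed=seed,
    )


def contrastive_debias(
    ds: EmbeddingDataset,
    attr: str,
    margin: float = 1.0,
    epochs: int = 100,
    learning_rate: float = 0.01,
    n_pairs: int = 2000,
    seed: int = 0,
) -> EmbeddingDataset:
    """Learn a linear map that pulls same-task cross-group pairs together
    and pushes different-task pairs apart (margin hinge on distances)."""
    a = check_binary_attribute(ds, attr)
    y = np.asarray(ds.task_labels, dtype=np.int64)
    if margin <= 0:
        log.warning("contrastive_debias: margin %.3g degenerate; returning identity", margin)
        return ds.replace_embeddings(ds.embeddings.copy())
    for yv in np.unique(y):
        for av in (0, 1):
            if ((y == yv) & (a == av)).sum() == 0:
                raise ValidationError(
                    f"contrastive_debias: no samples with Y={yv}, A={av} "
                    "(cross-group positive pairs unavailable)"
                )
    X = standardize(ds.embeddings)
    n, d = X.shape
    rng = np.random.default_rng(seed)

    pos_pairs = []  # same Y, different A: pull together
    neg_pairs = []  # different Y: push apart
    for _ in range(n_pairs):
        yv = int(rng.integers(0, 2)) if set(np.unique(y)) == {0, 1} else int(
            rng.choice(np.unique(y))
        )
        i = int(rng.choice(np.flatnonzero((y == yv) & (a == 0))))
        j = int(rng.choice(np.flatnonzero((y == yv) & (a == 1))))
        pos_pairs.append((i, j))
        i2 = int(rng.choice(np.flatnonzero(y == yv)))
        j2 = int(rng.choice(np.flatnonzero(y != yv)))
        neg_pairs.append((i2, j2))
    Dp = X[[p[0] for p in pos_pairs]] - X[[p[1] for p in pos_pairs]]
    Dn = X[[p[0] for p in neg_pairs]] - X[[p[1] for p in neg_pairs]]

    M = np.eye(d)
    for _ in range(epochs):
        Zp = Dp @ M
        Zn = Dn @ M
        # positive pairs: minimize squared distance
        gM = 2.0 * Dp.T @ Zp / len(Dp)
        # negative pairs: hinge on the distance falling under the margin
        dist = np.linalg.norm(Zn, axis=1)
        active = dist < margin
        if active.any():
            coef = -2.0 * (margin - dist[active]) / np.maximum(dist[active], 1e-9)
            gM += Dn[active].T @ (Zn[active] * coef[:, None]) / len(Dn)
        M -= learning_rate * gM
        if not np.isfinite(M).all():
            raise ValidationError("contrastive_debias diverged (non-finite map)")
    return ds.replace_embeddings(X @ M)


@dataclass
class MitigationResult:
    method: str
    transformed: EmbeddingDataset
    pre_report: AuditReport
    post_report: AuditReport
    task_utility_pre: float
    task_utility_post: float
    details: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "pre_report": self.pre_report.to_dict(),
            "post_report": self.post_report.to_dict(),
            "task_utility_pre": self.task_utility_pre,
            "task_utility_post": self.task_utility_post,
            "pre_agreement": f"{self.pre_report.agreement}/{self.pre_report.denominator}",
            "post_agreement": f"{self.post_report.agreement}/{self.post_report.denominator}",
            "details": self.details,
        }


def mitigate_and_reaudit(
    ds: EmbeddingDataset,
    attr: str,
    method: str,
    methods: Sequence[str] | None = None,
    seed: int = 0,
    config: Mapping[str, Any] | None = None,
    mask_dims: Sequence[int] | None = None,
    erasure_rounds: int = 3,
) -> MitigationResult:
    """Audit, apply one mitigation, re-audit with identical settings."""
    if method not in MITIGATION_METHODS:
        raise ValidationError(
            f"unknown mitigation {method!r}; use one of {MITIGATION_METHODS}"
        )
    cfg = dict(config or {})
    pre = run_audit(ds, attr, methods=methods, seed=seed, config=cfg)
    details: dict[str, Any] = {}

    if method == "dimension_masking":
        dims = mask_dims if mask_dims is not None else []
        transformed = mask_dimensions(ds, dims)
        details["masked_dims"] = sorted(int(i) for i in dims)
    elif method == "bias_direction_erasure":
        transformed = erase_bias_direction(ds, attr, rounds=erasure_rounds)
        details["rounds"] = erasure_rounds
    elif method == "adversarial_debias":
        transformed = adversarial_debias(ds, attr, seed=seed)
    elif method == "contrastive_debias":
        transformed = contrastive_debias(ds, attr, seed=seed)
    else:  # last_layer_retraining: head changes, embeddings do not
        transformed = ds.replace_embeddings(ds.embeddings.copy())
        retrained = last_layer_retrain(ds, attr, seed=seed)
        if retrained is None:
            raise ValidationError(
                "last_layer_retraining not applicable: a (Y, A) cell is too small"
            )
        details["retrained_accuracy"] = retrained.accuracy

    post = run_audit(transformed, attr, methods=methods, seed=seed, config=cfg)
    try:
        util_pre = fit_downstream(ds, seed=seed).accuracy
        util_post = fit_downstream(transformed, seed=seed).accuracy
    except ValidationError:
        util_pre = util_post = float("nan")
    return MitigationResult(
        method=method,
        transformed=transformed,
        pre_report=pre,
        post_report=post,
        task_utility_pre=util_pre,
        task_utility_post=util_post,
        details=details,
    )
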