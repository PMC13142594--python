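"""Embedding-native detectors.

Seven detectors interrogate the embedding geometry directly for
attribute structure:

* ``probe`` — cross-validated linear classifier A ~ E, flagged against a
  fixed high-risk accuracy cut and an empirical permutation chance
  threshold; localizes via robust z-scores of the refit coefficients.
* ``statistical`` — per-dimension Welch t-tests with multiple-testing
  correction; significant dimensions are the localization.
* ``geometric`` — permutation test of the distance between standardized
  group centroids.
* ``bias_direction`` — in-sample AUC of the projection onto the
  normalized centroid-difference direction.  Deliberately uncalibrated
  (in-sample, liberal cut): it flags on pure-noise embeddings, which is
  exactly the documented behavior the adjusted agreement counts correct
  for.
* ``frequency`` — per-dimension comparison of extreme-activation
  frequencies: how often each group's values exceed the pooled 95th
  percentile, tested per dimension with a two-proportion z-test and
  Bonferroni correction.  This is this package's embedding-level
  stand-in for frequency-based perturbation analysis and is labeled as
  such in reports.
* ``sis`` — greedy sufficient-subset search: forward selection of
  dimensions by in-sample accuracy of a linear scorer, flagged when a
  small subset suffices to predict A in-sample.  Also deliberately
  uncalibrated (in-sample).
* ``hbac`` — hierarchical bias-aware clustering: recursive bisecting
  2-means with per-leaf attribute-composition tests, score normalized by
  silhouette cluster-quality confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from ..calibration import correct_pvalues
from ..errors import ValidationError
from ..results import DetectorResult
from .base import check_binary_attribute, group_sizes, robust_z, standardize


@dataclass
class ProbeSettings:
    folds: int = 5
    flag_accuracy: float = 0.70
    localization_z: float = 3.0
    regularization_strength: float = 1.0
    permutations: int = 100
    chance_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValidationError("probe needs folds >= 2")
        if not (0.5 < self.flag_accuracy < 1.0):
            raise ValidationError("flag_accuracy must lie in (0.5, 1)")


@dataclass
class ClusterAudit:
    max_depth: int = 5
    min_cluster: int = 50
    composition_gap: float = 0.10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_cluster < 10:
            raise ValidationError("min_cluster must be >= 10")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")


def _probe_classifier(settings: ProbeSettings, seed: int) -> LogisticRegression:
    # loose tolerance: accuracy is indistinguishable from tight fits at
    # audit scale and the permutation null needs hundreds of refits
    return LogisticRegression(
        C=1.0 / settings.regularization_strength,
        solver="lbfgs",
        max_iter=100,
        tol=1e-2,
        random_state=seed,
    )


def _cv_balanced_accuracy(
    X: np.ndarray, a: np.ndarray, settings: ProbeSettings, seed: int
) -> float:
    cv = StratifiedKFold(settings.folds, shuffle=True, random_state=seed)
    clf = _probe_classifier(settings, seed)
    return float(
        cross_val_score(clf, X, a, cv=cv, scoring="balanced_accuracy").mean()
    )


def detect_probe(
    ds, attr: str, settings: ProbeSettings | None = None, seed: int = 0
) -> DetectorResult:
    """Linear probe: can a classifier recover A from E on held-out folds?

    Flags when the cross-validated balanced accuracy clears both the
    fixed high-risk cut (default 0.70) and the 95th percentile of a
    label-permutation null.
    """
    settings = settings or ProbeSettings()
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("probe", str(e))
    n0, n1 = group_sizes(a)
    if min(n0, n1) < settings.folds:
        return DetectorResult.not_applicable(
            "probe", f"minority class has {min(n0, n1)} samples < folds"
        )
    if ds.n < 10 * settings.folds:
        return DetectorResult.not_applicable(
            "probe", f"n={ds.n} < 10 x folds={settings.folds}"
        )
    X = standardize(ds.embeddings)
    acc = _cv_balanced_accuracy(X, a, settings, seed)

    rng = np.random.default_rng(seed)
    null = np.array(
        [
            _cv_balanced_accuracy(X, rng.permutation(a), settings, seed)
            for _ in range(settings.permutations)
        ]
    )
    chance_cut = float(np.quantile(null, settings.chance_quantile))

    score = float(np.clip((acc - 0.5) / 0.5, 0.0, 1.0))
    threshold = float(
        np.clip(
            (max(settings.flag_accuracy, chance_cut) - 0.5) / 0.5 - 1e-12, 0.0, 1.0
        )
    )
    flag = score > threshold

    coefs = _probe_classifier(settings, seed).fit(X, a).coef_[0]
    z = robust_z(coefs)
    localized = frozenset(np.flatnonzero(z >= settings.localization_z).tolist())
    return DetectorResult(
        method_name="probe",
        score=score,
        threshold=threshold,
        flag=flag,
        localized_dims=localized,
        details={
            "balanced_accuracy": acc,
            "chance_threshold": chance_cut,
            "flag_accuracy": settings.flag_accuracy,
            "permutations": settings.permutations,
            "seed": seed,
        },
    )


def detect_statistical(
    ds, attr: str, correction: str = "bonferroni", alpha: float = 0.05
) -> DetectorResult:
    """Per-dimension Welch two-sample t-tests across attribute groups."""
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("statistical", str(e))
    n0, n1 = group_sizes(a)
    if min(n0, n1) < 3:
        return DetectorResult.not_applicable(
            "statistical", f"each group needs >= 3 samples, got {n0}/{n1}"
        )
    E1, E0 = ds.embeddings[a == 1], ds.embeddings[a == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(E1, E0, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero within-group variance in a dimension: uninformative, p := 1
        p = np.where(degenerate, 1.0, p)
    p_adj = correct_pvalues(p, correction)
    sig = np.flatnonzero(p_adj <= alpha)
    min_p = float(p_adj.min())
    score = float(np.clip(1.0 - min_p, 0.0, 1.0))
    threshold = 1.0 - alpha
    return DetectorResult(
        method_name="statistical",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        localized_dims=frozenset(sig.tolist()),
        details={
            "correction": correction,
            "alpha": alpha,
            "min_corrected_p": min_p,
            "n_significant": int(sig.size),
            "n_degenerate_dims": int(degenerate.sum()),
        },
    )


def detect_geometric(
    ds, attr: str, permutations: int = 1000, alpha: float = 0.05, seed: int = 0
) -> DetectorResult:
    """Permutation test of the distance between standardized group centroids."""
    if permutations < 100:
        raise ValidationError("geometric test needs permutations >= 100")
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("geometric", str(e))
    n0, n1 = group_sizes(a)
    if min(n0, n1) < 2:
        return DetectorResult.not_applicable("geometric", "a group has < 2 samples")
    X = standardize(ds.embeddings)
    diff = X[a == 1].mean(axis=0) - X[a == 0].mean(axis=0)
    obs = float(np.linalg.norm(diff))

    rng = np.random.default_rng(seed)
    n = ds.n
    # vectorized permutation null: group-1 masks for all permutations at once
    perm_masks = np.empty((permutations, n), dtype=np.float64)
    for b in range(permutations):
        perm_masks[b] = rng.permutation(a)
    tot = X.sum(axis=0)
    s1 = perm_masks @ X  # (P, d) per-permutation group-1 sums
    cnt1 = perm_masks.sum(axis=1, keepdims=True)
    cnt0 = n - cnt1
    perm_diffs = s1 / cnt1 - (tot - s1) / cnt0
    perm_dist = np.linalg.norm(perm_diffs, axis=1)

    p = float((1 + (perm_dist >= obs).sum()) / (1 + permutations))
    score = 1.0 - p
    threshold = 1.0 - alpha
    # per-dimension localization against each dim's own permutation null
    dim_null = np.quantile(perm_diffs**2, 0.99, axis=0)
    localized = frozenset(np.flatnonzero(diff**2 > dim_null).tolist()) if score > threshold else frozenset()
    return DetectorResult(
        method_name="geometric",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        localized_dims=localized,
        details={
            "centroid_distance": obs,
            "p_value": p,
            "permutations": permutations,
            "seed": seed,
        },
    )


def detect_bias_direction(
    ds, attr: str, auc_threshold: float = 0.60, localization_z: float = 3.0
) -> DetectorResult:
    """In-sample AUC along the group centroid-difference direction.

    Uncalibrated by design: the direction is estimated and evaluated on
    the same samples, so on pure-noise embeddings the projection still
    separates the groups (AUC well above 0.5 at audit-scale n/d) and the
    detector flags.  Interpret only inside a convergence pipeline or via
    adjusted counts.
    """
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("bias_direction", str(e))
    if min(group_sizes(a)) < 2:
        return DetectorResult.not_applicable("bias_direction", "a group has < 2 samples")
    X = standardize(ds.embeddings)
    w = X[a == 1].mean(axis=0) - X[a == 0].mean(axis=0)
    norm = np.linalg.norm(w)
    if norm == 0:
        return DetectorResult.not_applicable(
            "bias_direction", "group centroids coincide; direction undefined"
        )
    w = w / norm
    auc = float(roc_auc_score(a, X @ w))
    score = float(np.clip(2.0 * (auc - 0.5), 0.0, 1.0))
    threshold = float(np.clip(2.0 * (auc_threshold - 0.5) - 1e-12, 0.0, 1.0))
    z = robust_z(w)
    localized = frozenset(np.flatnonzero(z >= localization_z).tolist())
    return DetectorResult(
        method_name="bias_direction",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        localized_dims=localized,
        details={"auc": auc, "auc_threshold": auc_threshold},
    )


def detect_frequency(
    ds,
    attr: str,
    correction: str = "bonferroni",
    alpha: float = 0.05,
    tail_quantile: float = 0.95,
) -> DetectorResult:
    """Extreme-activation frequency comparison per dimension.

    For each dimension, counts how often each group's values exceed the
    pooled ``tail_quantile`` cut and tests the two occupancy frequencies
    with a two-proportion z-test, corrected across dimensions.
    """
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("frequency", str(e))
    n0, n1 = group_sizes(a)
    if min(n0, n1) < 10:
        return DetectorResult.not_applicable(
            "frequency", f"groups too small for tail-frequency test ({n0}/{n1})"
        )
    E = ds.embeddings
    cut = np.quantile(E, tail_quantile, axis=0)
    tail = E > cut
    c1 = tail[a == 1].sum(axis=0)
    c0 = tail[a == 0].sum(axis=0)
    p1, p0 = c1 / n1, c0 / n0
    pooled = (c1 + c0) / (n1 + n0)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p0) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = correct_pvalues(p, correction)
    sig = np.flatnonzero(p_adj <= alpha)
    min_p = float(p_adj.min())
    score = float(np.clip(1.0 - min_p, 0.0, 1.0))
    threshold = 1.0 - alpha
    return DetectorResult(
        method_name="frequency",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        localized_dims=frozenset(sig.tolist()),
        details={
            "statistic": "tail-occupancy two-proportion z (stand-in for "
            "frequency-based perturbation)",
            "tail_quantile": tail_quantile,
            "correction": correction,
            "alpha": alpha,
            "min_corrected_p": min_p,
        },
    )


def detect_sis(
    ds,
    attr: str,
    max_subset: int = 20,
    target_accuracy: float = 0.55,
    seed: int = 0,
) -> DetectorResult:
    """Sufficient-input-subset search by greedy forward selection.

    At each step the dimension that maximizes the in-sample accuracy of
    a least-squares linear scorer on the selected subset is added; the
    search stops once the in-sample accuracy reaches ``target_accuracy``
    or ``max_subset`` dimensions.  In-sample by design, hence
    uncalibrated: greedy selection overfits enough that the target is
    reached even on pure-noise embeddings (the documented null behavior;
    the default target was frozen from a null-grid pilot).
    """
    if ds.d < 1:
        raise ValidationError("sis needs at least one dimension")
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("sis", str(e))
    if min(group_sizes(a)) < 2:
        return DetectorResult.not_applicable("sis", "a group has < 2 samples")
    X = standardize(ds.embeddings)
    n, d = X.shape
    y = (a - a.mean()).astype(float)

    # exact forward-stepwise least squares via Gram-Schmidt residualization;
    # candidate fits for every remaining dim are evaluated in one matrix op
    Xr = X.copy()
    fit = np.zeros(n)
    resid = y.copy()
    selected: list[int] = []
    acc_path: list[float] = []
    max_subset = min(max_subset, d)
    for _ in range(max_subset):
        norms = np.einsum("ij,ij->j", Xr, Xr)
        dead = norms <= 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            coefs = np.where(dead, 0.0, (Xr.T @ resid) / np.where(dead, 1.0, norms))
        cand_fit = fit[:, None] + Xr * coefs
        acc = ((cand_fit > 0) == (a[:, None] == 1)).mean(axis=0)
        acc = np.maximum(acc, 1.0 - acc)
        acc[selected] = -1.0
        acc[dead] = -1.0
        j = int(np.argmax(acc))  # ties broken by lowest index (argmax is first)
        if acc[j] < 0:
            break
        selected.append(j)
        q = Xr[:, j] / np.sqrt(norms[j])
        fit = fit + q * (q @ resid)
        resid = y - fit
        Xr = Xr - np.outer(q, q @ Xr)
        step_acc = ((fit > 0) == (a == 1)).mean()
        acc_path.append(float(max(step_acc, 1.0 - step_acc)))
        if acc_path[-1] >= target_accuracy:
            break

    final_acc = acc_path[-1] if acc_path else 0.5
    score = float(np.clip((final_acc - 0.5) / 0.5, 0.0, 1.0))
    threshold = float(np.clip((target_accuracy - 0.5) / 0.5 - 1e-12, 0.0, 1.0))
    return DetectorResult(
        method_name="sis",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        localized_dims=frozenset(selected),
        details={
            "final_accuracy": float(final_acc),
            "target_accuracy": target_accuracy,
            "subset_size": len(selected),
            "accuracy_path": [round(v, 4) for v in acc_path],
        },
    )


def detect_hbac(
    ds, attr: str, settings: ClusterAudit | None = None, seed: int = 0
) -> DetectorResult:
    """Hierarchical bias-aware clustering.

    Recursive bisecting 2-means on standardized embeddings; each leaf's
    attribute composition is tested against the global composition
    (two-proportion z, Bonferroni over leaves).  The evidence score is
    the largest significant composition gap weighted by the positive
    part of the leaf partition's silhouette (cluster-quality confidence).
    """
    settings = settings or ClusterAudit()
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("hbac", str(e))
    if ds.n < 2 * settings.min_cluster:
        return DetectorResult.not_applicable(
            "hbac", f"n={ds.n} < 2 x min_cluster={settings.min_cluster}"
        )
    X = standardize(ds.embeddings)

    leaves: list[np.ndarray] = []

    def split(idx: np.ndarray, depth: int) -> None:
        if depth >= settings.max_depth or idx.size < 2 * settings.min_cluster:
            leaves.append(idx)
            return
        km = KMeans(n_clusters=2, n_init=3, random_state=seed).fit(X[idx])
        left, right = idx[km.labels_ == 0], idx[km.labels_ == 1]
        if left.size < settings.min_cluster or right.size < settings.min_cluster:
            leaves.append(idx)
            return
        split(left, depth + 1)
        split(right, depth + 1)

    split(np.arange(ds.n), 0)
    if len(leaves) < 2:
        return DetectorResult.not_applicable(
            "hbac", "clustering produced fewer than 2 leaves"
        )

    labels = np.empty(ds.n, dtype=int)
    for li, idx in enumerate(leaves):
        labels[idx] = li
    sil = float(silhouette_score(X, labels))
    sil_pos = max(sil, 0.0)

    p_global = a.mean()
    m = len(leaves)
    best_gap = 0.0
    best_leaf = None
    leaf_stats = []
    for li, idx in enumerate(leaves):
        p_c = a[idx].mean()
        se = np.sqrt(p_global * (1.0 - p_global) / idx.size)
        z = (p_c - p_global) / se if se > 0 else 0.0
        p_corr = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        gap = abs(p_c - p_global)
        leaf_stats.append(
            {"size": int(idx.size), "composition": float(p_c),
             "gap": float(gap), "p_corrected": float(p_corr)}
        )
        if p_corr <= settings.alpha and gap > best_gap:
            best_gap = gap
            best_leaf = li

    score = float(np.clip(sil_pos * best_gap / 0.5, 0.0, 1.0))
    threshold = float(np.clip(sil_pos * settings.composition_gap / 0.5 - 1e-12, 0.0, 1.0))
    flag = score > threshold
    localized: frozenset[int] = frozenset()
    if flag and best_leaf is not None:
        centroid_diff = np.abs(X[leaves[best_leaf]].mean(axis=0) - X.mean(axis=0))
        cut = np.quantile(centroid_diff, 0.90)
        localized = frozenset(np.flatnonzero(centroid_diff >= cut).tolist())
    return DetectorResult(
        method_name="hbac",
        score=score,
        threshold=threshold,
        flag=flag,
        localized_dims=localized,
        details={
            "n_leaves": m,
            "silhouette": sil,
            "max_significant_gap": float(best_gap),
            "global_composition": float(p_global),
            "leaves": leaf_stats,
            "seed": seed,
        },
    )
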