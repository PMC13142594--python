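"""Learning-dynamics detectors.

GroupDRO, GCE and SSA train small linear task heads on the embeddings
and read shortcut reliance out of the training behavior — worst-group
loss dynamics, the attribute alignment of an easy-example-amplifying
loss, and pseudo-labeled attribute error gaps.  None of them looks at
embedding geometry directly: when the task labels are independent of the
embeddings (as in the synthetic benchmark) there is no loss structure to
exploit, and these detectors stay silent no matter how strongly the
attribute is encoded.

All training loops are deterministic full-batch gradient descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from ..data import EmbeddingDataset
from ..errors import ValidationError
from ..results import DetectorResult
from .base import check_binary_attribute, standardize


@dataclass
class DynamicsSettings:
    epochs: int = 50
    learning_rate: float = 0.1
    dro_eta: float = 0.1
    gce_q: float = 0.7
    ssa_labeled_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if not (0.0 < self.gce_q <= 1.0):
            raise ValidationError("gce_q must lie in (0, 1]")
        if not (0.0 < self.ssa_labeled_fraction < 1.0):
            raise ValidationError("ssa_labeled_fraction must lie in (0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _ce_loss(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    # per-sample logistic loss, numerically stable
    return np.logaddexp(0.0, z) - y * z


def gce_loss(p_true: np.ndarray, q: float) -> np.ndarray:
    """Generalized cross-entropy L_q(p) = (1 - p^q) / q.

    Interpolates between cross-entropy (q -> 0) and 0-1-like loss
    (q = 1); intermediate q down-weights hard examples so the fit is
    dominated by the easy (shortcut-aligned) ones.
    """
    p_true = np.asarray(p_true, dtype=float)
    return (1.0 - p_true**q) / q


def _train_logistic_gd(
    X: np.ndarray,
    y: np.ndarray,
    settings: DynamicsSettings,
    sample_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Full-batch GD on weighted logistic loss; returns (w, b)."""
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    sw = np.full(n, 1.0 / n) if sample_weights is None else sample_weights
    for _ in range(settings.epochs):
        z = X @ w + b
        g = (_sigmoid(z) - y) * sw
        w -= settings.learning_rate * (X.T @ g)
        b -= settings.learning_rate * g.sum()
    return w, b


def detect_group_dro(
    ds: EmbeddingDataset,
    attr: str,
    settings: DynamicsSettings | None = None,
    seed: int = 0,
) -> DetectorResult:
    """Compare ERM and GroupDRO task heads over attribute groups.

    GroupDRO reweights groups by exponentiated accumulated loss (step
    ``dro_eta``).  A shortcut shows up as (a) the DRO weights collapsing
    onto one group and (b) DRO repairing the worst-group loss that ERM
    incurs; both must hold for a flag.
    """
    settings = settings or DynamicsSettings()
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("group_dro", str(e))
    y = np.asarray(ds.task_labels, dtype=float)
    if len(np.unique(y)) < 2:
        return DetectorResult.not_applicable("group_dro", "single-class task labels")
    X = standardize(ds.embeddings)
    n = len(y)
    groups = [a == 0, a == 1]
    if any(m.sum() == 0 for m in groups):
        return DetectorResult.not_applicable("group_dro", "empty attribute group")

    w_erm, b_erm = _train_logistic_gd(X, y, settings)
    z = X @ w_erm + b_erm
    erm_group_losses = [float(_ce_loss(z[m], y[m]).mean()) for m in groups]

    # GroupDRO: exponentiated-gradient ascent on group weights
    q = np.array([0.5, 0.5])
    w = np.zeros(X.shape[1])
    b = 0.0
    max_share = 0.5
    for _ in range(settings.epochs):
        zz = X @ w + b
        losses = np.array([_ce_loss(zz[m], y[m]).mean() for m in groups])
        q = q * np.exp(settings.dro_eta * losses)
        q = q / q.sum()
        # once DRO equalizes group losses the weights drift back toward
        # uniform, so the collapse signal is the peak share over training
        max_share = max(max_share, float(q.max()))
        sw = np.zeros(n)
        for g, m in enumerate(groups):
            sw[m] = q[g] / m.sum()
        g_vec = (_sigmoid(zz) - y) * sw
        w -= settings.learning_rate * (X.T @ g_vec)
        b -= settings.learning_rate * g_vec.sum()
    zz = X @ w + b
    dro_group_losses = [float(_ce_loss(zz[m], y[m]).mean()) for m in groups]

    weight_share = max_share
    loss_gap = max(erm_group_losses) - max(dro_group_losses)
    score = float(np.clip(loss_gap / 0.5, 0.0, 1.0))
    share_cut = 0.5 + 0.1  # G = 2
    threshold = 0.1 / 0.5 if weight_share > share_cut else 1.0
    return DetectorResult(
        method_name="group_dro",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        details={
            "erm_group_losses": erm_group_losses,
            "dro_group_losses": dro_group_losses,
            "dro_weight_share": weight_share,  # peak share over training
            "worst_group_loss_gap": float(loss_gap),
            "epochs": settings.epochs,
            "learning_rate": settings.learning_rate,
            "dro_eta": settings.dro_eta,
        },
    )


def detect_gce(
    ds: EmbeddingDataset,
    attr: str,
    settings: DynamicsSettings | None = None,
    seed: int = 0,
    alignment_threshold: float = 0.60,
) -> DetectorResult:
    """Attribute alignment of a generalized-cross-entropy task head.

    A GCE-trained head latches onto the easiest predictive structure; if
    that structure is the attribute shortcut, its held-out task
    predictions track A.  The signal is the balanced accuracy of those
    predictions in predicting A.
    """
    settings = settings or DynamicsSettings()
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("gce", str(e))
    y = np.asarray(ds.task_labels, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        return DetectorResult.not_applicable("gce", "single-class task labels")
    folds = 5
    if counts.min() < folds:
        return DetectorResult.not_applicable(
            "gce", f"smallest task class has {counts.min()} < {folds} samples"
        )
    X = standardize(ds.embeddings)
    n = len(y)
    qexp = settings.gce_q

    preds = np.empty(n, dtype=np.int64)
    cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    for train, test in cv.split(X, y):
        w = np.zeros(X.shape[1])
        b = 0.0
        Xt, yt = X[train], y[train]
        for _ in range(settings.epochs):
            z = Xt @ w + b
            p = _sigmoid(z)
            p_true = np.where(yt == 1, p, 1.0 - p)
            p_true = np.clip(p_true, 1e-12, 1.0)
            s = np.where(yt == 1, 1.0, -1.0)
            # d L_q / d z = -s * p_true^q * (1 - p_true)
            g = -s * (p_true**qexp) * (1.0 - p_true) / len(train)
            w -= settings.learning_rate * (Xt.T @ g)
            b -= settings.learning_rate * g.sum()
        preds[test] = ((X[test] @ w + b) > 0).astype(np.int64)

    align = float(
        max(
            balanced_accuracy_score(a, preds),
            balanced_accuracy_score(a, 1 - preds),
        )
    )
    # gate on task skill: a head that cannot predict Y at all emits
    # near-random predictions whose incidental attribute alignment is not
    # evidence of shortcut reliance
    task_acc = float(balanced_accuracy_score(y, preds))
    gated = align if task_acc >= 0.55 else 0.5
    score = float(np.clip((gated - 0.5) / 0.5, 0.0, 1.0))
    threshold = float((alignment_threshold - 0.5) / 0.5 - 1e-12)
    return DetectorResult(
        method_name="gce",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        details={
            "attribute_alignment": align,
            "task_balanced_accuracy": task_acc,
            "alignment_threshold": alignment_threshold,
            "gce_q": qexp,
            "epochs": settings.epochs,
            "seed": seed,
        },
    )


def detect_ssa(
    ds: EmbeddingDataset,
    attr: str,
    settings: DynamicsSettings | None = None,
    seed: int = 0,
    pseudo_accuracy_threshold: float = 0.70,
    error_gap_threshold: float = 0.10,
) -> DetectorResult:
    """Semi-supervised spurious-attribute estimation via pseudo-labeling.

    Only a small labeled fraction of A is used to train an attribute
    classifier; the rest is pseudo-labeled.  Flags when the pseudo-labels
    are accurate (the attribute is learnable from few labels) AND the
    downstream task model's error rate differs across pseudo-attribute
    groups — i.e. the attribute partition predicts task failure.
    """
    settings = settings or DynamicsSettings()
    try:
        a = check_binary_attribute(ds, attr)
    except ValidationError as e:
        return DetectorResult.not_applicable("ssa", str(e))
    y = np.asarray(ds.task_labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        return DetectorResult.not_applicable("ssa", "single-class task labels")
    n = ds.n
    n_labeled = int(round(settings.ssa_labeled_fraction * n))
    if n_labeled < 20:
        return DetectorResult.not_applicable(
            "ssa", f"labeled fraction yields {n_labeled} samples (< 20)"
        )
    X = standardize(ds.embeddings)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labeled, hidden = order[:n_labeled], order[n_labeled:]
    if len(np.unique(a[labeled])) < 2:
        return DetectorResult.not_applicable(
            "ssa", "labeled subset contains a single attribute class"
        )
    clf = LogisticRegression(max_iter=100, tol=1e-2, random_state=seed)
    clf.fit(X[labeled], a[labeled])
    pseudo = np.asarray(a, dtype=np.int64).copy()
    pseudo[hidden] = clf.predict(X[hidden])
    pseudo_acc = float((pseudo[hidden] == a[hidden]).mean())

    # downstream task head, held-out predictions, error per pseudo-group
    from .fairness import fit_downstream

    try:
        model = fit_downstream(ds, seed=seed)
    except ValidationError as e:
        return DetectorResult.not_applicable("ssa", f"downstream model: {e}")
    err = (model.predictions != y).astype(float)
    if (pseudo == 0).sum() == 0 or (pseudo == 1).sum() == 0:
        return DetectorResult.not_applicable("ssa", "pseudo-labels collapse to one group")
    err_gap = abs(float(err[pseudo == 0].mean()) - float(err[pseudo == 1].mean()))

    gated = err_gap if pseudo_acc >= pseudo_accuracy_threshold else 0.0
    score = float(np.clip(gated / 0.3, 0.0, 1.0))
    threshold = float(error_gap_threshold / 0.3)
    return DetectorResult(
        method_name="ssa",
        score=score,
        threshold=threshold,
        flag=score > threshold,
        details={
            "pseudo_label_accuracy": pseudo_acc,
            "pseudo_accuracy_threshold": pseudo_accuracy_threshold,
            "task_error_gap": err_gap,
            "error_gap_threshold": error_gap_threshold,
            "n_labeled": n_labeled,
            "seed": seed,
        },
    )
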