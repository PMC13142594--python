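"""Audit orchestration: run a set of detectors on (E, Y, A) and aggregate.

The common detector contract is ``detect(E, Y, A) -> DetectorResult``;
this module dispatches each canonical method name to its implementation,
derives a per-detector seed from the audit seed, and folds the resulting
flags into an :class:`~shortcut_audit.results.AuditReport`.
"""

from __future__ import annotations

import logging
import time
from typing import Any, Sequence

import numpy as np

from .calibration import AggregationPolicy, aggregate
from .config import default_config, merge_config
from .data import EmbeddingDataset
from .detectors.base import CANONICAL_ORDER, derive_seed
from .detectors.dynamics import (
    DynamicsSettings,
    detect_gce,
    detect_group_dro,
    detect_ssa,
)
from .detectors.fairness import (
    detect_demographic_parity,
    detect_equalized_odds,
    detect_intersectional,
    fit_downstream,
)
from .detectors.representation import (
    ClusterAudit,
    ProbeSettings,
    detect_bias_direction,
    detect_frequency,
    detect_geometric,
    detect_hbac,
    detect_probe,
    detect_sis,
    detect_statistical,
)
from .errors import ValidationError
from .results import AuditReport, DetectorResult

log = logging.getLogger("shortcut_audit")


def run_detector(
    name: str,
    ds: EmbeddingDataset,
    attr: str,
    all_attrs: Sequence[str],
    cfg: dict[str, Any],
    seed: int,
    downstream=None,
) -> DetectorResult:
    """Run one canonical detector; returns its DetectorResult."""
    det_cfg = cfg.get("detectors", {})
    dseed = derive_seed(seed, name)

    if name == "probe":
        return detect_probe(
            ds, attr, ProbeSettings(**det_cfg.get("probe", {})), seed=dseed
        )
    if name == "statistical":
        c = det_cfg.get("statistical", {})
        return detect_statistical(
            ds, attr, c.get("correction", "bonferroni"), c.get("alpha", 0.05)
        )
    if name == "geometric":
        c = det_cfg.get("geometric", {})
        return detect_geometric(
            ds,
            attr,
            permutations=c.get("permutations", 1000),
            alpha=c.get("alpha", 0.05),
            seed=dseed,
        )
    if name == "bias_direction":
        c = det_cfg.get("bias_direction", {})
        return detect_bias_direction(ds, attr, c.get("auc_threshold", 0.60))
    if name == "frequency":
        c = det_cfg.get("frequency", {})
        return detect_frequency(
            ds,
            attr,
            correction=c.get("correction", "bonferroni"),
            alpha=c.get("alpha", 0.05),
            tail_quantile=c.get("tail_quantile", 0.95),
        )
    if name == "sis":
        c = det_cfg.get("sis", {})
        return detect_sis(
            ds,
            attr,
            max_subset=c.get("max_subset", 20),
            target_accuracy=c.get("target_accuracy", 0.55),
            seed=dseed,
        )
    if name == "hbac":
        return detect_hbac(
            ds, attr, ClusterAudit(**det_cfg.get("hbac", {})), seed=dseed
        )
    if name == "demographic_parity":
        c = det_cfg.get("demographic_parity", {})
        if downstream is None:
            return DetectorResult.not_applicable(name, "no downstream model")
        return detect_demographic_parity(
            downstream, ds, attr, epsilon=c.get("epsilon", 0.01)
        )
    if name == "equalized_odds":
        c = det_cfg.get("equalized_odds", {})
        if downstream is None:
            return DetectorResult.not_applicable(name, "no downstream model")
        return detect_equalized_odds(
            downstream,
            ds,
            attr,
            gap_threshold=c.get("gap_threshold", 0.10),
            permutations=c.get("permutations", 200),
            seed=dseed,
        )
    if name == "intersectional":
        c = det_cfg.get("intersectional", {})
        if downstream is None:
            return DetectorResult.not_applicable(name, "no downstream model")
        return detect_intersectional(
            downstream,
            ds,
            list(all_attrs),
            epsilon=c.get("epsilon", 0.01),
            min_cell=c.get("min_cell", 20),
        )
    dyn = DynamicsSettings(**det_cfg.get("dynamics", {}))
    if name == "group_dro":
        return detect_group_dro(ds, attr, dyn, seed=dseed)
    if name == "gce":
        return detect_gce(ds, attr, dyn, seed=dseed)
    if name == "ssa":
        return detect_ssa(ds, attr, dyn, seed=dseed)
    raise ValidationError(
        f"unknown method {name!r}; valid methods: {list(CANONICAL_ORDER)}"
    )


def run_audit(
    ds: EmbeddingDataset,
    attr: str,
    methods: Sequence[str] | None = None,
    seed: int = 0,
    config: dict[str, Any] | None = None,
    all_attrs: Sequence[str] | None = None,
) -> AuditReport:
    """Audit one attribute with the requested methods (default: all 13).

    ``all_attrs`` feeds the intersectional detector; it defaults to all
    attributes in the dataset.
    """
    cfg = merge_config(default_config(), config or {})
    methods = list(methods) if methods is not None else list(CANONICAL_ORDER)
    unknown = [m for m in methods if m not in CANONICAL_ORDER]
    if unknown:
        raise ValidationError(
            f"unknown method(s) {unknown}; valid: {list(CANONICAL_ORDER)}"
        )
    # keep canonical order regardless of request order
    methods = [m for m in CANONICAL_ORDER if m in methods]
    all_attrs = list(all_attrs) if all_attrs is not None else sorted(ds.attributes)

    needs_downstream = {
        "demographic_parity", "equalized_odds", "intersectional", "ssa",
    }
    downstream = None
    if needs_downstream & set(methods):
        try:
            downstream = fit_downstream(ds, seed=derive_seed(seed, "downstream"))
        except ValidationError as e:
            log.warning("downstream model unavailable: %s", e)

    results: list[DetectorResult] = []
    for name in methods:
        t0 = time.perf_counter()
        try:
            res = run_detector(name, ds, attr, all_attrs, cfg, seed, downstream)
        except ValidationError:
            raise
        except Exception as e:  # detector failure is recorded, never silent
            log.warning("detector %s failed: %s", name, e)
            res = DetectorResult.not_applicable(name, f"detector error: {e}")
        log.info(
            "detector %-18s seed=%d wall=%.3fs flag=%s",
            name, derive_seed(seed, name), time.perf_counter() - t0, res.flag,
        )
        results.append(res)

    policy = AggregationPolicy(**cfg.get("aggregation", {}))
    agg = aggregate(results, policy)
    a = ds.attribute(attr)
    classes, counts = np.unique(a, return_counts=True)
    summary = {
        "n": ds.n,
        "d": ds.d,
        "attribute": attr,
        "attributes_available": all_attrs,
        "class_counts": {int(c): int(k) for c, k in zip(classes, counts)},
    }
    return AuditReport(
        dataset_summary=summary,
        results=results,
        agreement=agg.agreement,
        denominator=agg.denominator,
        risk_score=agg.risk_score,
        convergence_level=agg.convergence_level,
        adjusted_agreement=agg.adjusted_agreement,
        adjusted_denominator=agg.adjusted_denominator,
        seed=seed,
        config_echo=cfg,
    )
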