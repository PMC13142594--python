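"""Multiple-testing correction, permutation chance thresholds, bootstrap
CIs, and aggregation of detector flags into a risk score and convergence
level.

Aggregation follows the indicator-count rule

    R = (1/|M|) * sum_m 1[s_m > tau_m]

over the applicable methods M.  The convergence bands generalize the
HIGH >= 7/12 rule as a fraction applied by ceiling to any denominator;
the adjusted counts remove the three detectors (bias-direction, SIS,
demographic parity) whose default thresholds are deliberately
uncalibrated and flag on null data, giving the adjusted denominator 10
for a full 13-method audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import EmbeddingDataset
from .errors import ValidationError
from .results import ConvergenceLevel, DetectorResult

CORRECTIONS = ("bonferroni", "holm", "fdr_bh")

#: detectors excluded from the adjusted agreement counts
UNCALIBRATED_TRIO = frozenset({"bias_direction", "sis", "demographic_parity"})


def correct_pvalues(p: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Adjust a vector of p-values for multiple comparisons.

    ``bonferroni``: min(1, m*p_i); ``holm``: step-down; ``fdr_bh``:
    Benjamini-Hochberg step-up with monotonicity enforcement.  Output
    order matches input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in CORRECTIONS:
        raise ValidationError(f"unknown correction {method!r}; use one of {CORRECTIONS}")
    return multipletests(p, method=method)[1]


def chance_threshold(
    ds: EmbeddingDataset,
    attr: str,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    permutations: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Empirical chance threshold for a probe-like statistic.

    Recomputes ``statistic(E, A_perm)`` under independent permutations of
    the attribute labels and returns the requested quantile of that null
    distribution.  Deterministic given ``seed``.
    """
    if permutations < 50:
        raise ValidationError("chance_threshold needs permutations >= 50")
    if not (0.0 < quantile < 1.0):
        raise ValidationError("quantile must lie strictly in (0, 1)")
    a = ds.attribute(attr)
    rng = np.random.default_rng(seed)
    null = np.array(
        [statistic(ds.embeddings, rng.permutation(a)) for _ in range(permutations)]
    )
    return float(np.quantile(null, quantile))


def bootstrap_ci(
    values: Sequence[float],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean of per-seed values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("bootstrap_ci needs at least 2 values")
    if B < 100:
        raise ValidationError("bootstrap_ci needs B >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class AggregationPolicy:
    """Convergence banding and adjusted-count exclusions."""

    high_fraction: float = 7.0 / 12.0
    moderate_fraction: float = 5.0 / 12.0
    excluded_from_adjusted: frozenset[str] = field(default=UNCALIBRATED_TRIO)

    def __post_init__(self) -> None:
        if not (0.0 < self.moderate_fraction < self.high_fraction <= 1.0):
            raise ValidationError(
                "need 0 < moderate_fraction < high_fraction <= 1"
            )
        self.excluded_from_adjusted = frozenset(self.excluded_from_adjusted)

    def required(self, fraction: float, denominator: int) -> int:
        # ceiling with a small guard against float noise in fraction*den
        return max(1, math.ceil(fraction * denominator - 1e-9))

    def level(self, agreement: int, denominator: int) -> ConvergenceLevel:
        if agreement >= self.required(self.high_fraction, denominator):
            return ConvergenceLevel.HIGH
        if agreement >= self.required(self.moderate_fraction, denominator):
            return ConvergenceLevel.MODERATE
        if agreement >= 1:
            return ConvergenceLevel.LOW
        return ConvergenceLevel.NONE


@dataclass
class Aggregation:
    agreement: int
    denominator: int
    risk_score: float
    convergence_level: ConvergenceLevel
    adjusted_agreement: int
    adjusted_denominator: int


def aggregate(
    results: Sequence[DetectorResult],
    policy: AggregationPolicy | None = None,
) -> Aggregation:
    """Indicator-count aggregation over the applicable detector results."""
    policy = policy or AggregationPolicy()
    applicable = [r for r in results if r.applicable]
    if not applicable:
        raise ValidationError("no applicable detectors to aggregate")
    agreement = sum(r.flag for r in applicable)
    denominator = len(applicable)
    adj = [r for r in applicable if r.method_name not in policy.excluded_from_adjusted]
    return Aggregation(
        agreement=agreement,
        denominator=denominator,
        risk_score=agreement / denominator,
        convergence_level=policy.level(agreement, denominator),
        adjusted_agreement=sum(r.flag for r in adj),
        adjusted_denominator=len(adj),
    )
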