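"""Synthetic benchmark with ground-truth shortcut dimensions.

The generator emulates the statistical structure the detectors assume:
every dimension is i.i.d. standard normal, then a sparse subset of ``k``
dimensions is mean-shifted between two attribute groups by a chosen
Cohen's d (group 1 by +delta/2, group 0 by -delta/2, so the
standardized group mean difference per shortcut dimension equals
``delta``).  Task labels are drawn independently of both embeddings and
attribute, so any detection is a pure embedding-attribute shortcut
signal and learning-dynamics detectors have nothing to latch onto.

delta = 0 produces null embeddings for empirical false-positive-rate
estimation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .audit import run_detector
from .calibration import bootstrap_ci
from .data import EmbeddingDataset
from .detectors.base import SYNTHETIC_SUITE, derive_seed
from .detectors.fairness import fit_downstream
from .errors import ValidationError
from .results import DetectorResult

log = logging.getLogger("shortcut_audit")


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark generator parameters.

    delta is the per-dimension Cohen's d of the group mean shift on the
    k shortcut-carrying dimensions; imbalance is the majority-group
    proportion of the sensitive attribute; label_rate is P(Y=1) with Y
    independent of everything else.
    """

    n: int = 1000
    d: int = 128
    delta: float = 0.8
    k: int = 10
    imbalance: float = 0.5
    label_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.d):
            raise ValidationError(f"need 1 <= k={self.k} <= d={self.d}")
        if not (0.0 < self.imbalance < 1.0):
            raise ValidationError("imbalance must lie in (0, 1)")
        if not (0.0 < self.label_rate < 1.0):
            raise ValidationError("label_rate must lie in (0, 1)")
        if self.n < 4:
            raise ValidationError("n must be >= 4")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return SyntheticConfig(
            n=self.n, d=self.d, delta=self.delta, k=self.k,
            imbalance=self.imbalance, label_rate=self.label_rate, seed=seed,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "n": self.n, "d": self.d, "delta": self.delta, "k": self.k,
            "imbalance": self.imbalance, "label_rate": self.label_rate,
            "seed": self.seed,
        }


@dataclass
class SyntheticDataset:
    dataset: EmbeddingDataset
    true_dims: frozenset[int]
    config: SyntheticConfig


def generate_synthetic(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic dataset; bit-reproducible from ``config.seed``.

    Uses one named child RNG stream per logical draw (attribute,
    embeddings, shortcut dims, labels) so adding draws later cannot
    silently shift existing streams.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_a, rng_e, rng_dims, rng_y = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    n, d, k = config.n, config.d, config.k
    # group 0 is the majority group with proportion `imbalance`
    a = (rng_a.random(n) >= config.imbalance).astype(np.int64)
    E = rng_e.standard_normal((n, d))
    true_dims = np.sort(rng_dims.choice(d, size=k, replace=False))
    shift = np.where(a == 1, config.delta / 2.0, -config.delta / 2.0)
    E[:, true_dims] += shift[:, None]
    y = (rng_y.random(n) < config.label_rate).astype(np.int64)
    ds = EmbeddingDataset(
        embeddings=E,
        task_labels=y,
        attributes={"group": a},
        sample_ids=[f"syn{config.seed}_{i}" for i in range(n)],
    )
    return SyntheticDataset(
        dataset=ds, true_dims=frozenset(int(i) for i in true_dims), config=config
    )


def score_localization(
    detected: Sequence[int] | frozenset[int],
    true_dims: Sequence[int] | frozenset[int],
    d: int | None = None,
) -> tuple[float, float, float]:
    """Precision/recall/F1 of detected vs true shortcut dimensions.

    Empty detected and empty truth scores (1, 1, 1); empty detected with
    nonempty truth scores (0, 0, 0).
    """
    det = {int(i) for i in detected}
    true = {int(i) for i in true_dims}
    if d is not None:
        bad = [i for i in det | true if not (0 <= i < d)]
        if bad:
            raise ValidationError(f"dimension indices out of range [0, {d}): {bad}")
    if any(i < 0 for i in det | true):
        raise ValidationError("dimension indices must be non-negative")
    if not det and not true:
        return 1.0, 1.0, 1.0
    tp = len(det & true)
    precision = tp / len(det) if det else 0.0
    recall = tp / len(true) if true else 1.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


#: detectors whose localization is scored against true_dims
LOCALIZING_METHODS = frozenset(
    {"probe", "statistical", "geometric", "bias_direction", "sis"}
)


@dataclass
class BenchmarkTable:
    """Per-(method, config) detection and localization summary over seeds."""

    rows: list[dict[str, Any]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.rows, fh, indent=2, sort_keys=True)
        return path

    def detection_rate(self, method: str, **config_fields: Any) -> float:
        for row in self.rows:
            if row["method"] == method and all(
                row[k] == v for k, v in config_fields.items()
            ):
                return row["detection_rate"]
        raise KeyError(f"no row for method={method}, {config_fields}")


def run_suite(
    syn: SyntheticDataset,
    methods: Sequence[str] = SYNTHETIC_SUITE,
    audit_seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> dict[str, DetectorResult]:
    """Run the listed detectors on one synthetic dataset."""
    from .config import default_config, merge_config

    cfg = merge_config(default_config(), dict(config or {}))
    ds = syn.dataset
    seed = syn.config.seed if audit_seed is None else audit_seed
    needs_downstream = {"demographic_parity", "equalized_odds", "intersectional", "ssa"}
    downstream = None
    if needs_downstream & set(methods):
        downstream = fit_downstream(ds, seed=derive_seed(seed, "downstream"))
    out: dict[str, DetectorResult] = {}
    for name in methods:
        try:
            out[name] = run_detector(
                name, ds, "group", ["group"], cfg, seed, downstream
            )
        except ValidationError:
            raise
        except Exception as e:
            log.warning(
                "benchmark: detector %s failed on seed %d: %s", name, seed, e
            )
            out[name] = DetectorResult.not_applicable(name, f"detector error: {e}")
    return out


def run_benchmark_grid(
    grid: Sequence[SyntheticConfig],
    methods: Sequence[str] = SYNTHETIC_SUITE,
    seeds: int = 10,
    config: Mapping[str, Any] | None = None,
    ci_bootstrap: int = 1000,
) -> BenchmarkTable:
    """Run each config over ``seeds`` replicates and tabulate.

    Replicate seeds form the ladder base, base+1, ...; localization F1 is
    scored against the generator's true dimensions for the localizing
    methods.  A detector failure on one seed is recorded as
    not-applicable for that cell (warned, never silently dropped).
    """
    if seeds < 1:
        raise ValidationError("seeds must be >= 1")
    table = BenchmarkTable()
    for cfg in grid:
        per_method: dict[str, dict[str, list]] = {
            m: {"flags": [], "prec": [], "rec": [], "f1": [], "applicable": []}
            for m in methods
        }
        for i in range(seeds):
            syn = generate_synthetic(cfg.with_seed(cfg.seed + i))
            results = run_suite(syn, methods, config=config)
            for m, res in results.items():
                rec = per_method[m]
                rec["applicable"].append(res.applicable)
                rec["flags"].append(bool(res.flag))
                if m in LOCALIZING_METHODS and res.localized_dims is not None:
                    p, r, f1 = score_localization(
                        res.localized_dims, syn.true_dims, d=cfg.d
                    )
                    rec["prec"].append(p)
                    rec["rec"].append(r)
                    rec["f1"].append(f1)
        for m in methods:
            rec = per_method[m]
            flags = np.asarray(rec["flags"], dtype=float)
            rate = float(flags.mean())
            if seeds >= 2 and ci_bootstrap >= 100:
                lo, hi = bootstrap_ci(flags, B=ci_bootstrap, seed=cfg.seed)
            else:
                lo = hi = float("nan")
            row: dict[str, Any] = {
                "method": m,
                **cfg.to_dict(),
                "seeds": seeds,
                "n_applicable": int(sum(rec["applicable"])),
                "detection_rate": rate,
                "ci_low": lo,
                "ci_high": hi,
            }
            if rec["f1"]:
                for key, vals in (("precision", rec["prec"]),
                                  ("recall", rec["rec"]), ("f1", rec["f1"])):
                    arr = np.asarray(vals)
                    row[f"{key}_mean"] = float(arr.mean())
                    row[f"{key}_sd"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            table.rows.append(row)
    return table


AGGREGATIONS = ("per_method", "indicator_count", "convergence_high")


def estimate_fpr(
    config_null: SyntheticConfig,
    methods: Sequence[str] = SYNTHETIC_SUITE,
    seeds: int = 10,
    aggregation: str = "per_method",
    config: Mapping[str, Any] | None = None,
    high_fraction: float = 7.0 / 12.0,
) -> dict[str, float]:
    """Empirical false-positive rates on null embeddings (delta = 0).

    ``per_method`` returns one FPR per detector; ``indicator_count``
    flags a seed when any detector flags; ``convergence_high`` flags a
    seed when at least ceil(high_fraction x denominator) detectors flag.
    """
    import math

    if config_null.delta != 0:
        raise ValidationError("estimate_fpr requires a null config (delta == 0)")
    if aggregation not in AGGREGATIONS:
        raise ValidationError(
            f"unknown aggregation {aggregation!r}; use one of {AGGREGATIONS}"
        )
    flags_per_seed: list[dict[str, bool]] = []
    denoms: list[int] = []
    for i in range(seeds):
        syn = generate_synthetic(config_null.with_seed(config_null.seed + i))
        results = run_suite(syn, methods, config=config)
        flags_per_seed.append(
            {m: bool(r.flag) for m, r in results.items() if r.applicable}
        )
        denoms.append(sum(r.applicable for r in results.values()))
    if aggregation == "per_method":
        return {
            m: float(np.mean([f.get(m, False) for f in flags_per_seed]))
            for m in methods
        }
    if aggregation == "indicator_count":
        hits = [sum(f.values()) >= 1 for f in flags_per_seed]
        return {"indicator_count": float(np.mean(hits))}
    hits = [
        sum(f.values()) >= math.ceil(high_fraction * den - 1e-9)
        for f, den in zip(flags_per_seed, denoms)
    ]
    return {"convergence_high": float(np.mean(hits))}
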