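"""Result containers: per-detector evidence and the aggregated audit report.

Every detector returns a :class:`DetectorResult` holding its normalized
evidence score ``s_m`` in [0, 1], its method-specific threshold ``tau_m``
and the flag ``s_m > tau_m``.  :class:`AuditReport` aggregates the flags
into an agreement count, the risk score R = agreement / |M| and a
convergence level, plus the adjusted counts that exclude the three
detectors documented to flag on null data.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Any

from .errors import ValidationError

SPEC_VERSION = "1"


class ConvergenceLevel(str, enum.Enum):
    NONE = "NONE"
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


@dataclass
class DetectorResult:
    """One detector's output for one (dataset, attribute) audit."""

    method_name: str
    score: float | None
    threshold: float
    flag: bool
    localized_dims: frozenset[int] | None = None
    details: dict[str, Any] = field(default_factory=dict)
    applicable: bool = True

    def __post_init__(self) -> None:
        if self.applicable:
            if self.score is None:
                raise ValidationError(
                    f"{self.method_name}: applicable result needs a score"
                )
            if not (0.0 <= self.score <= 1.0):
                raise ValidationError(
                    f"{self.method_name}: score {self.score} outside [0, 1]"
                )
            if self.flag != (self.score > self.threshold):
                raise ValidationError(
                    f"{self.method_name}: flag {self.flag} inconsistent with "
                    f"score {self.score} vs threshold {self.threshold}"
                )
        else:
            self.score = None
            self.flag = False
        if self.localized_dims is not None:
            self.localized_dims = frozenset(int(i) for i in self.localized_dims)

    @classmethod
    def not_applicable(
        cls, method_name: str, reason: str, threshold: float = 1.0
    ) -> "DetectorResult":
        return cls(
            method_name=method_name,
            score=None,
            threshold=threshold,
            flag=False,
            applicable=False,
            details={"reason": reason},
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "method_name": self.method_name,
            "score": self.score,
            "threshold": self.threshold,
            "flag": self.flag,
            "localized_dims": (
                sorted(self.localized_dims) if self.localized_dims is not None else None
            ),
            "details": _jsonable(self.details),
            "applicable": self.applicable,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DetectorResult":
        dims = d.get("localized_dims")
        return cls(
            method_name=d["method_name"],
            score=d["score"],
            threshold=d["threshold"],
            flag=d["flag"],
            localized_dims=frozenset(dims) if dims is not None else None,
            details=d.get("details", {}),
            applicable=d.get("applicable", True),
        )


@dataclass
class AuditReport:
    """Aggregated multi-detector audit of one attribute."""

    dataset_summary: dict[str, Any]
    results: list[DetectorResult]
    agreement: int
    denominator: int
    risk_score: float
    convergence_level: ConvergenceLevel
    adjusted_agreement: int
    adjusted_denominator: int
    seed: int
    config_echo: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.denominator > 0 and self.risk_score != self.agreement / self.denominator:
            raise ValidationError(
                "risk_score must equal agreement/denominator exactly"
            )
        if not (0 <= self.adjusted_agreement <= self.adjusted_denominator
                <= self.denominator):
            raise ValidationError(
                "adjusted counts must satisfy 0 <= adj_agree <= adj_den <= den"
            )
        if isinstance(self.convergence_level, str):
            self.convergence_level = ConvergenceLevel(self.convergence_level)

    def to_dict(self) -> dict[str, Any]:
        return {
            "spec_version": SPEC_VERSION,
            "dataset_summary": _jsonable(self.dataset_summary),
            "results": [r.to_dict() for r in self.results],
            "agreement": self.agreement,
            "denominator": self.denominator,
            "risk_score": self.risk_score,
            "convergence_level": self.convergence_level.value,
            "adjusted_agreement": self.adjusted_agreement,
            "adjusted_denominator": self.adjusted_denominator,
            "seed": self.seed,
            "config_echo": _jsonable(self.config_echo),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AuditReport":
        return cls(
            dataset_summary=d["dataset_summary"],
            results=[DetectorResult.from_dict(r) for r in d["results"]],
            agreement=d["agreement"],
            denominator=d["denominator"],
            risk_score=d["risk_score"],
            convergence_level=ConvergenceLevel(d["convergence_level"]),
            adjusted_agreement=d["adjusted_agreement"],
            adjusted_denominator=d["adjusted_denominator"],
            seed=d["seed"],
            config_echo=d.get("config_echo", {}),
        )

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "AuditReport":
        return cls.from_dict(json.loads(text))


def _jsonable(obj: Any) -> Any:
    """Recursively coerce numpy scalars/arrays and sets to JSON-native types."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, enum.Enum):
        return obj.value
    return obj
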