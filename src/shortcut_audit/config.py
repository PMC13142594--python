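"""Configuration defaults, YAML overlay, and resolution.

Every run echoes its fully resolved configuration into the report so a
reader never has to guess which thresholds were in force.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

from .errors import SchemaError


def default_config() -> dict[str, Any]:
    """All tunables with their frozen defaults, fully materialized."""
    return {
        "detectors": {
            "probe": {
                "folds": 5,
                "flag_accuracy": 0.70,
                "localization_z": 3.0,
                "regularization_strength": 1.0,
                "permutations": 100,
                "chance_quantile": 0.95,
            },
            "statistical": {"correction": "bonferroni", "alpha": 0.05},
            "geometric": {"permutations": 1000, "alpha": 0.05},
            "bias_direction": {"auc_threshold": 0.60},
            "frequency": {
                "correction": "bonferroni",
                "alpha": 0.05,
                "tail_quantile": 0.95,
            },
            "sis": {"max_subset": 20, "target_accuracy": 0.55},
            "hbac": {
                "max_depth": 5,
                "min_cluster": 50,
                "composition_gap": 0.10,
                "alpha": 0.05,
            },
            "demographic_parity": {"epsilon": 0.01},
            "equalized_odds": {"gap_threshold": 0.10, "permutations": 200},
            "intersectional": {"epsilon": 0.01, "min_cell": 20},
            "dynamics": {
                "epochs": 50,
                "learning_rate": 0.1,
                "dro_eta": 0.1,
                "gce_q": 0.7,
                "ssa_labeled_fraction": 0.1,
            },
        },
        "aggregation": {
            "high_fraction": 7.0 / 12.0,
            "moderate_fraction": 5.0 / 12.0,
            "excluded_from_adjusted": [
                "bias_direction",
                "sis",
                "demographic_parity",
            ],
        },
    }


def merge_config(base: dict[str, Any], overlay: dict[str, Any]) -> dict[str, Any]:
    """Deep-merge ``overlay`` into a copy of ``base``."""
    out = copy.deepcopy(base)

    def _merge(dst: dict[str, Any], src: dict[str, Any]) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                _merge(dst[k], v)
            else:
                dst[k] = v

    _merge(out, overlay)
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"config {path} must be a YAML mapping")
    return data
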