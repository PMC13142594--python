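"""Shared detector plumbing: canonical method registry, seed derivation,
and small numeric helpers used by several detectors."""

from __future__ import annotations

import zlib

import numpy as np

from ..data import EmbeddingDataset
from ..errors import ValidationError

#: canonical 13-method order (fixed for report diffability)
CANONICAL_ORDER = (
    "hbac",
    "probe",
    "statistical",
    "geometric",
    "frequency",
    "bias_direction",
    "sis",
    "demographic_parity",
    "equalized_odds",
    "intersectional",
    "group_dro",
    "gce",
    "ssa",
)

#: the 12-method suite used on single-attribute synthetic benchmarks
SYNTHETIC_SUITE = tuple(m for m in CANONICAL_ORDER if m != "intersectional")

DISPLAY_NAMES = {
    "hbac": "HBAC",
    "probe": "Probe",
    "statistical": "Statistical",
    "geometric": "Geometric",
    "frequency": "Frequency",
    "bias_direction": "BiasDir",
    "sis": "SIS",
    "demographic_parity": "DP",
    "equalized_odds": "EO",
    "intersectional": "Intersectional",
    "group_dro": "GroupDRO",
    "gce": "GCE",
    "ssa": "SSA",
}


def derive_seed(audit_seed: int, method_name: str) -> int:
    """Stable per-detector seed from the audit seed and the method name."""
    h = zlib.crc32(method_name.encode("utf-8"))
    return int((audit_seed * 1_000_003 + h) % (2**31))


def standardize(X: np.ndarray) -> np.ndarray:
    """Pooled per-dimension z-scoring; constant dimensions map to 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def robust_z(values: np.ndarray) -> np.ndarray:
    """|x - median| / (1.4826 * MAD); zeros if the MAD vanishes."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad <= 0:
        return np.zeros_like(values)
    return np.abs(values - med) / (1.4826 * mad)


def check_binary_attribute(ds: EmbeddingDataset, attr: str) -> np.ndarray:
    """Fetch an attribute and confirm it is binary {0,1}; returns int array."""
    a = np.asarray(ds.attribute(attr), dtype=np.int64)
    vals = set(np.unique(a))
    if not vals <= {0, 1}:
        raise ValidationError(
            f"attribute {attr!r} must be binary {{0,1}}, found levels {sorted(vals)}"
        )
    return a


def group_sizes(a: np.ndarray) -> tuple[int, int]:
    return int((a == 0).sum()), int((a == 1).sum())
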