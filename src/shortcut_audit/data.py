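"""Core dataset container and embedding/metadata I/O.

An audit operates on the triple (E, Y, A): an ``n x d`` real embedding
matrix ``E``, integer task labels ``Y`` and one or more named sensitive
attributes ``A`` (binary after encoding).  ``EmbeddingDataset`` carries
that triple plus sample/dimension bookkeeping; the readers below accept
NPY, CSV and Parquet embeddings and CSV metadata.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

log = logging.getLogger("shortcut_audit")

EMBEDDING_FORMATS = ("npy", "csv", "parquet")

#: default cut for binarizing age-like numeric attribute columns (>= cut -> 1)
DEFAULT_AGE_CUT = 60.0


@dataclass
class EmbeddingDataset:
    """The audited triple (E, Y, A) with bookkeeping.

    Attributes
    ----------
    embeddings : ndarray, shape (n, d)
        Real-valued embedding matrix, one row per sample.
    task_labels : ndarray, shape (n,)
        Integer task labels Y (binary {0,1} or a small categorical set).
    attributes : dict of str -> ndarray
        Named sensitive attributes, each an integer vector of length n
        (binary after encoding).
    sample_ids : list of str
        One identifier per row.
    dim_names : list of str or None
        Optional names for the d embedding dimensions.
    """

    embeddings: np.ndarray
    task_labels: np.ndarray
    attributes: dict[str, np.ndarray]
    sample_ids: list[str] = field(default_factory=list)
    dim_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.task_labels = np.asarray(self.task_labels)
        self.attributes = {k: np.asarray(v) for k, v in self.attributes.items()}
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.embeddings.shape[0])]

    @property
    def n(self) -> int:
        return int(self.embeddings.shape[0])

    @property
    def d(self) -> int:
        return int(self.embeddings.shape[1])

    def attribute(self, name: str) -> np.ndarray:
        if name not in self.attributes:
            raise SchemaError(
                f"unknown attribute {name!r}; have {sorted(self.attributes)}"
            )
        return self.attributes[name]

    def subset(self, rows: np.ndarray) -> "EmbeddingDataset":
        """Row-subset preserving order; ``rows`` is an index or boolean mask."""
        rows = np.asarray(rows)
        ids = list(np.asarray(self.sample_ids, dtype=object)[rows])
        return EmbeddingDataset(
            embeddings=self.embeddings[rows],
            task_labels=self.task_labels[rows],
            attributes={k: v[rows] for k, v in self.attributes.items()},
            sample_ids=[str(s) for s in ids],
            dim_names=self.dim_names,
        )

    def replace_embeddings(self, embeddings: np.ndarray) -> "EmbeddingDataset":
        return dataclasses.replace(self, embeddings=np.asarray(embeddings, float))


def _read_csv_matrix(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Comma-separated numeric matrix; a first row with any non-numeric
    token is taken as a header of dimension names."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    first = lines[0].split(",")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    dim_names: list[str] | None = None
    start = 0
    if not all(_numeric(t) for t in first):
        dim_names = [t.strip() for t in first]
        start = 1
    rows: list[list[float]] = []
    width: int | None = None
    for i, ln in enumerate(lines[start:], start=start):
        toks = ln.split(",")
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise FormatError(
                f"{path}: ragged row {i} (expected {width} columns, got {len(toks)})"
            )
        row = []
        for j, tok in enumerate(toks):
            try:
                row.append(float(tok))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {tok!r}"
                ) from None
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=np.float64), dim_names


def read_embeddings(
    path: str | Path, format: str | None = None
) -> tuple[np.ndarray, list[str] | None]:
    """Read an ``n x d`` embedding matrix from NPY, CSV or Parquet.

    Returns ``(matrix, dim_names)``; ``dim_names`` is None unless the file
    carries column names (CSV header / Parquet schema).  Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"embedding file not found: {path}")
    if format is None:
        format = {".npy": "npy", ".csv": "csv", ".parquet": "parquet"}.get(
            path.suffix.lower(), "csv"
        )
    if format not in EMBEDDING_FORMATS:
        raise ValidationError(
            f"unknown embedding format {format!r}; expected one of {EMBEDDING_FORMATS}"
        )
    dim_names: list[str] | None = None
    if format == "npy":
        X = np.load(path)
        if X.ndim != 2:
            raise FormatError(f"{path}: expected a 2-D array, got ndim={X.ndim}")
        if not np.issubdtype(X.dtype, np.number):
            raise FormatError(f"{path}: non-numeric dtype {X.dtype}")
        X = X.astype(np.float64)
    elif format == "csv":
        X, dim_names = _read_csv_matrix(path)
    else:  # parquet
        df = pd.read_parquet(path)
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise FormatError(f"{path}: non-numeric parquet columns {bad}")
        dim_names = [str(c) for c in df.columns]
        X = df.to_numpy(dtype=np.float64)
    if X.shape[0] < 4 or X.shape[1] < 2:
        raise ValidationError(
            f"embedding matrix too small: n={X.shape[0]} (need >=4), "
            f"d={X.shape[1]} (need >=2)"
        )
    return X, dim_names


def write_embeddings(X: np.ndarray, path: str | Path, format: str) -> Path:
    """Inverse of :func:`read_embeddings` for the three supported formats."""
    path = Path(path)
    X = np.asarray(X, dtype=np.float64)
    if format == "npy":
        np.save(path, X)
    elif format == "csv":
        np.savetxt(path, X, delimiter=",", fmt="%.17g")
    elif format == "parquet":
        pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])]).to_parquet(path)
    else:
        raise ValidationError(f"unknown embedding format {format!r}")
    return path


def _encode_attribute(
    col: pd.Series,
    name: str,
    level_map: Mapping[str, int] | None,
    age_cut: float,
) -> np.ndarray:
    """Encode one attribute column to {0,1} with NaN kept for later dropping.

    Rules: an explicit level map wins; two-level columns map the
    lexicographically smaller raw value to 0; numeric columns with more
    than two distinct values are binarized at ``age_cut`` (>= cut -> 1).
    """
    vals = col.dropna().unique()
    if level_map is not None:
        out = col.map(lambda v: level_map.get(v, np.nan) if pd.notna(v) else np.nan)
        enc = out.to_numpy(dtype=float)
        levels = set(enc[~np.isnan(enc)])
        if len(levels) < 2:
            raise ValidationError(
                f"attribute {name!r}: level map yields a single level {levels}"
            )
        return enc
    if len(vals) < 2:
        raise ValidationError(
            f"attribute {name!r} has a single level {vals[:1].tolist()}; "
            "binary attributes need both classes present"
        )
    if len(vals) == 2:
        lo, hi = sorted(vals, key=str)
        return col.map({lo: 0, hi: 1}).to_numpy(dtype=float)
    if pd.api.types.is_numeric_dtype(col):
        enc = (col.to_numpy(dtype=float) >= age_cut).astype(float)
        enc[col.isna().to_numpy()] = np.nan
        if len(set(enc[~np.isnan(enc)])) < 2:
            raise ValidationError(
                f"attribute {name!r}: binarization at cut {age_cut} "
                "leaves a single level"
            )
        return enc
    raise ValidationError(
        f"attribute {name!r} has {len(vals)} levels and no level map; "
        "supply an explicit binarization map for multi-level categorical attributes"
    )


def read_metadata(
    path: str | Path,
    task_col: str,
    attr_cols: Sequence[str],
    level_maps: Mapping[str, Mapping[str, int]] | None = None,
    age_cut: float = DEFAULT_AGE_CUT,
) -> tuple[np.ndarray, dict[str, np.ndarray], list[str]]:
    """Read the metadata CSV and encode task + attribute columns.

    Returns ``(task_labels, attributes, sample_ids)``.  Attribute vectors
    are float arrays holding {0, 1, NaN}; rows with NaN are dropped later
    by :func:`validate_dataset` (never imputed).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"metadata file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in [task_col, *attr_cols] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"metadata {path} is missing column(s) {missing}; "
            f"available: {list(df.columns)}"
        )
    level_maps = level_maps or {}
    task = _encode_attribute(df[task_col], task_col, level_maps.get(task_col), age_cut)
    if np.isnan(task).any():
        raise ValidationError(
            f"task column {task_col!r} has {int(np.isnan(task).sum())} missing values"
        )
    attrs = {
        c: _encode_attribute(df[c], c, level_maps.get(c), age_cut) for c in attr_cols
    }
    if "sample_id" in df.columns:
        ids = [str(s) for s in df["sample_id"]]
    else:
        ids = [f"s{i}" for i in range(len(df))]
    return task.astype(np.int64), attrs, ids


@dataclass
class ValidationSummary:
    n_rows_in: int
    n_rows_out: int
    n_dropped_missing: int
    messages: list[str] = field(default_factory=list)


def validate_dataset(
    ds: EmbeddingDataset,
) -> tuple[EmbeddingDataset, ValidationSummary]:
    """Enforce dataset invariants; drop (and log) rows with missing attributes.

    Raises :class:`ValidationError` listing every violation found.
    Idempotent: validating the returned dataset again is a no-op.
    """
    problems: list[str] = []
    E = ds.embeddings
    n = E.shape[0] if E.ndim == 2 else -1
    if E.ndim != 2:
        problems.append(f"embeddings must be 2-D, got ndim={E.ndim}")
    if n >= 0 and len(ds.task_labels) != n:
        problems.append(
            f"task_labels length {len(ds.task_labels)} != n rows {n}"
        )
    if n >= 0 and len(ds.sample_ids) != n:
        problems.append(f"sample_ids length {len(ds.sample_ids)} != n rows {n}")
    for name, a in ds.attributes.items():
        if len(a) != n:
            problems.append(f"attribute {name!r} length {len(a)} != n rows {n}")
    if ds.dim_names is not None and E.ndim == 2 and len(ds.dim_names) != E.shape[1]:
        problems.append(
            f"dim_names length {len(ds.dim_names)} != d columns {E.shape[1]}"
        )
    if E.ndim == 2 and not np.isfinite(E).all():
        r, c = np.argwhere(~np.isfinite(E))[0]
        k = int((~np.isfinite(E)).sum())
        problems.append(
            f"embeddings contain {k} non-finite value(s), first at row {r}, col {c}"
        )
    if problems:
        raise ValidationError("; ".join(problems))

    # drop rows with missing attribute values (logged, never imputed)
    keep = np.ones(n, dtype=bool)
    for a in ds.attributes.values():
        af = np.asarray(a, dtype=float)
        keep &= ~np.isnan(af)
    dropped = int(n - keep.sum())
    out = ds if dropped == 0 else ds.subset(keep)
    out = EmbeddingDataset(
        embeddings=out.embeddings,
        task_labels=np.asarray(out.task_labels, dtype=np.int64),
        attributes={
            k: np.asarray(v, dtype=np.int64) for k, v in out.attributes.items()
        },
        sample_ids=out.sample_ids,
        dim_names=out.dim_names,
    )
    messages = []
    if dropped:
        messages.append(f"dropped {dropped} row(s) with missing attribute values")
        log.info("validate_dataset: %s", messages[-1])

    post: list[str] = []
    if out.n < 4:
        post.append(f"n={out.n} after dropping missing rows (need >=4)")
    if out.d < 2:
        post.append(f"d={out.d} (need >=2)")
    for name, a in out.attributes.items():
        vals, counts = np.unique(a, return_counts=True)
        if len(vals) < 2:
            post.append(f"attribute {name!r} has a single class after dropping")
        elif len(vals) == 2 and counts.min() < 2:
            post.append(
                f"attribute {name!r} has only {counts.min()} sample(s) in its "
                "smaller class (need >=2)"
            )
    if post:
        raise ValidationError("; ".join(post))
    return out, ValidationSummary(n, out.n, dropped, messages)


def load_dataset(
    embeddings_path: str | Path,
    metadata_path: str | Path,
    task_col: str,
    attr_cols: Sequence[str],
    embedding_format: str | None = None,
    level_maps: Mapping[str, Mapping[str, int]] | None = None,
    age_cut: float = DEFAULT_AGE_CUT,
) -> tuple[EmbeddingDataset, ValidationSummary]:
    """Convenience loader: embeddings + metadata -> validated dataset."""
    X, dim_names = read_embeddings(embeddings_path, embedding_format)
    task, attrs, ids = read_metadata(
        metadata_path, task_col, attr_cols, level_maps=level_maps, age_cut=age_cut
    )
    if len(task) != X.shape[0]:
        raise ValidationError(
            f"embeddings have {X.shape[0]} rows but metadata has {len(task)}"
        )
    ds = EmbeddingDataset(
        embeddings=X,
        task_labels=task,
        attributes=attrs,
        sample_ids=ids,
        dim_names=dim_names,
    )
    return validate_dataset(ds)
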