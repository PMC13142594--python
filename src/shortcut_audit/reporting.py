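"""Rendered audit and benchmark reports: JSON, Markdown, and the
detection-rate heatmap figure."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .detectors.base import CANONICAL_ORDER, DISPLAY_NAMES
from .errors import ValidationError
from .results import AuditReport
from .synthetic import BenchmarkTable


def render_markdown(report: AuditReport) -> str:
    """Deterministic Markdown audit report; detector rows in canonical order."""
    if not report.results:
        raise ValidationError("no applicable detectors: empty results list")
    by_name = {r.method_name: r for r in report.results}
    ordered = [by_name[m] for m in CANONICAL_ORDER if m in by_name]
    extra = [r for r in report.results if r.method_name not in CANONICAL_ORDER]
    ordered += extra

    lines = []
    s = report.dataset_summary
    lines.append(f"# Shortcut audit: attribute `{s.get('attribute', '?')}`")
    lines.append("")
    lines.append(
        f"Dataset: n={s.get('n')}, d={s.get('d')}; "
        f"class counts {s.get('class_counts')}; seed {report.seed}."
    )
    lines.append("")
    lines.append("| Method | Flag | Score | Threshold | Localized dims |")
    lines.append("|---|---|---|---|---|")
    for r in ordered:
        flag = "✓" if r.flag else "·"
        score = f"{r.score:.3f}" if r.score is not None else "n/a"
        dims = (
            ", ".join(str(i) for i in sorted(r.localized_dims))
            if r.localized_dims
            else "–"
        )
        name = DISPLAY_NAMES.get(r.method_name, r.method_name)
        if not r.applicable:
            name += " (n/a)"
        lines.append(f"| {name} | {flag} | {score} | {r.threshold:.3f} | {dims} |")
    lines.append("")
    lines.append(f"Agreement: **{report.agreement}/{report.denominator}**")
    lines.append(
        f"Adjusted agreement (excluding uncalibrated detectors "
        f"{sorted(report.config_echo.get('aggregation', {}).get('excluded_from_adjusted', []))}): "
        f"**{report.adjusted_agreement}/{report.adjusted_denominator}**"
    )
    lines.append(f"Risk score R = {report.risk_score:.4f}")
    lines.append(f"Convergence level: **{report.convergence_level.value}**")
    lines.append("")
    return "\n".join(lines)


def write_report(
    report: AuditReport,
    out_dir: str | Path,
    formats: Iterable[str] = ("json", "markdown"),
    stem: str = "audit_report",
) -> list[Path]:
    """Write the report as JSON (lossless round-trip) and/or Markdown."""
    if not report.results:
        raise ValidationError("no applicable detectors: empty results list")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: list[Path] = []
        for fmt in formats:
            if fmt == "json":
                p = out_dir / f"{stem}.json"
                p.write_text(report.to_json(), encoding="utf-8")
            elif fmt == "markdown":
                p = out_dir / f"{stem}.md"
                p.write_text(render_markdown(report), encoding="utf-8")
            else:
                raise ValidationError(f"unknown report format {fmt!r}")
            paths.append(p)
        return paths
    except OSError as e:
        raise IOError(f"cannot write report to {out_dir}: {e}") from e


def render_benchmark_markdown(table: BenchmarkTable) -> str:
    """Markdown view of a benchmark table: detection rate by method x delta."""
    df = table.to_dataframe()
    deltas = sorted(df["delta"].unique())
    lines = ["# Synthetic benchmark: detection rates", ""]
    lines.append("| Method | " + " | ".join(f"δ={d:g}" for d in deltas) + " |")
    lines.append("|---" * (len(deltas) + 1) + "|")
    for m in CANONICAL_ORDER:
        sub = df[df["method"] == m]
        if sub.empty:
            continue
        cells = []
        for d in deltas:
            row = sub[sub["delta"] == d]
            cells.append(f"{row['detection_rate'].iloc[0]:.2f}" if len(row) else "—")
        lines.append(
            f"| {DISPLAY_NAMES.get(m, m)} | " + " | ".join(cells) + " |"
        )
    lines.append("")
    return "\n".join(lines)


def plot_convergence_matrix(
    table: BenchmarkTable,
    path: str | Path,
    methods: Sequence[str] | None = None,
):
    """Detection-rate heatmap (methods x effect size), a pure view of the
    benchmark table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    df = table.to_dataframe()
    deltas = sorted(df["delta"].unique())
    methods = list(methods) if methods else [
        m for m in CANONICAL_ORDER if m in set(df["method"])
    ]
    mat = np.full((len(methods), len(deltas)), np.nan)
    for i, m in enumerate(methods):
        for j, d in enumerate(deltas):
            row = df[(df["method"] == m) & (df["delta"] == d)]
            if len(row):
                mat[i, j] = row["detection_rate"].iloc[0]
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.9 * len(deltas), 1.0 + 0.42 * len(methods))
    )
    im = ax.imshow(mat, cmap="Greens", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(deltas)), [f"δ={d:g}" for d in deltas])
    ax.set_yticks(range(len(methods)), [DISPLAY_NAMES.get(m, m) for m in methods])
    for i in range(len(methods)):
        for j in range(len(deltas)):
            if np.isfinite(mat[i, j]):
                ax.text(
                    j, i, f"{mat[i, j]:.2f}", ha="center", va="center",
                    fontsize=8, color="black" if mat[i, j] < 0.6 else "white",
                )
    ax.set_title("Detection rate across effect sizes")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_benchmark(
    table: BenchmarkTable, out_dir: str | Path, figure: bool = True
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [
        table.write_csv(out_dir / "benchmark.csv"),
        table.write_json(out_dir / "benchmark.json"),
    ]
    md = out_dir / "benchmark.md"
    md.write_text(render_benchmark_markdown(table), encoding="utf-8")
    paths.append(md)
    if figure:
        paths.append(plot_convergence_matrix(table, out_dir / "convergence_matrix.png"))
    return paths


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
    return path
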