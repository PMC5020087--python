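"""Statistical graphics for SSR classification tables.

Each classification gets a bar chart (and a pie chart for the unit-length
distribution); per-sequence counts are drawn as a scatter of SSR count
against sequence length, which for well-assembled genomes is close to
linear.  Rendering is deterministic (fixed DPI, no embedded timestamps) so
outputs can be compared byte-for-byte across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "ssrforge"  # reproducible SVG ids

import matplotlib.pyplot as plt
import pandas as pd

from .sequence_io import PathLike

SUPPORTED_FORMATS = ("png", "svg")


class PlottingError(ValueError):
    """Empty table or unsupported configuration."""


@dataclass
class PlotConfig:
    outdir: PathLike = "."
    formats: Sequence[str] = ("png", "svg")
    width: float = 7.0
    height: float = 5.0
    dpi: int = 150
    palette: str = "tab20"

    def __post_init__(self) -> None:
        bad = [f for f in self.formats if f not in SUPPORTED_FORMATS]
        if bad:
            raise PlottingError(f"unsupported formats {bad}; use {SUPPORTED_FORMATS}")
        Path(self.outdir).mkdir(parents=True, exist_ok=True)


def _save(fig, stem: str, config: PlotConfig) -> List[Path]:
    paths = []
    for fmt in config.formats:
        path = Path(config.outdir) / f"{stem}.{fmt}"
        metadata = {"Date": None} if fmt == "svg" else {}
        fig.savefig(path, dpi=config.dpi, format=fmt, metadata=metadata)
        paths.append(path)
    plt.close(fig)
    return paths


def _check(table: pd.DataFrame, what: str) -> None:
    if table is None or len(table) == 0:
        raise PlottingError(f"cannot plot empty {what} table")


def _colors(n: int, config: PlotConfig):
    cmap = plt.get_cmap(config.palette)
    return [cmap(i % cmap.N) for i in range(n)]


def plot_unit_length(table: pd.DataFrame, config: PlotConfig) -> List[Path]:
    """Unit-length (mer) distribution as both a bar chart and a pie chart."""
    _check(table, "unit-length")
    labels = [f"{u}-mer" for u in table.iloc[:, 0]]
    counts = table["Count"].to_numpy()
    colors = _colors(len(labels), config)

    fig, ax = plt.subplots(figsize=(config.width, config.height))
    ax.bar(labels, counts, color=colors)
    ax.set_xlabel("Motif unit length")
    ax.set_ylabel("SSR count")
    ax.set_title("Motif type distribution")
    out = _save(fig, "unit_length_bar", config)

    fig, ax = plt.subplots(figsize=(config.height, config.height))
    ax.pie(counts, labels=labels, colors=colors, autopct="%.2f%%", startangle=90)
    ax.set_title("Motif type distribution")
    out += _save(fig, "unit_length_pie", config)
    return out


def plot_motif_nucleotides(table: pd.DataFrame, config: PlotConfig, top: int = 30) -> List[Path]:
    """Motif-composition distribution, bars ranked descending by count."""
    _check(table, "motif")
    head = table.head(top)
    fig, ax = plt.subplots(figsize=(config.width, config.height))
    ax.bar(head["Motif"], head["Count"], color=_colors(len(head), config))
    ax.set_xlabel("Motif")
    ax.set_ylabel("SSR count")
    ax.set_title("Motif composition")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    return _save(fig, "motif_bar", config)


def plot_length_distribution(table: pd.DataFrame, config: PlotConfig) -> List[Path]:
    """SSR tract-length distribution over the observed length range."""
    _check(table, "length")
    ordered = table.sort_values(table.columns[0]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(config.width, config.height))
    ax.bar(ordered.iloc[:, 0], ordered["Count"], color="#4878a8")
    ax.set_xlabel("SSR length (bp)")
    ax.set_ylabel("SSR count")
    ax.set_title("SSR length distribution")
    return _save(fig, "ssr_length_bar", config)


def plot_count_vs_length(table: pd.DataFrame, config: PlotConfig) -> List[Path]:
    """Scatter of SSR count vs sequence length, one point per sequence."""
    _check(table, "frequency")
    if len(table) < 2:
        raise PlottingError("count-vs-length plot needs at least 2 sequences")
    fig, ax = plt.subplots(figsize=(config.width, config.height))
    ax.scatter(table["Length"], table["Count"], color="#a84848", zorder=3)
    ax.set_xlabel("Sequence length (bp)")
    ax.set_ylabel("SSR count")
    ax.set_title("SSR count vs sequence length")
    ax.grid(True, alpha=0.3)
    return _save(fig, "count_vs_length", config)


def plot_all(report, config: PlotConfig) -> List[Path]:
    """Render every figure the report's tables allow; skip empty inputs."""
    out: List[Path] = []
    if len(report.unit_length):
        out += plot_unit_length(report.unit_length, config)
    if len(report.motif):
        out += plot_motif_nucleotides(report.motif, config)
    if len(report.length):
        out += plot_length_distribution(report.length, config)
    if len(report.frequency) >= 2:
        out += plot_count_vs_length(report.frequency, config)
    return out
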