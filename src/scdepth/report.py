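"""Figures and summary tables for benchmark results.

Every figure is backed by a TSV table written by the pipeline, so the
numbers remain testable without parsing images. Figure panels mirror the
benchmark's standard views: tSNE + cluster frequency bars, sequencing-
metric curves against read depth, accuracy against depth/cell number
with a 90% reference line, and the median-accuracy heatmap.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_tsne_frequency",
    "plot_depth_metrics",
    "plot_accuracy_curves",
    "plot_accuracy_heatmap",
    "make_report",
]

GRID_TSV = "benchmark_grid.tsv"
DEPTH_TSV = "depth_metrics.tsv"
TSNE_TSV = "tsne.tsv"


def plot_tsne_frequency(tsne: pd.DataFrame, out_path) -> None:
    """Scatter coloured by cluster with a cluster-frequency bar panel.

    ``tsne`` columns: tsne_1, tsne_2, cluster."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4), width_ratios=[2, 1])
    for cid, grp in tsne.groupby("cluster"):
        ax1.scatter(grp["tsne_1"], grp["tsne_2"], s=4, label=str(cid))
    ax1.set_xlabel("tSNE 1")
    ax1.set_ylabel("tSNE 2")
    ax1.legend(title="cluster", fontsize=6, markerscale=2)
    freq = tsne["cluster"].value_counts(normalize=True).sort_index()
    ax2.bar(freq.index.astype(str), freq.to_numpy())
    ax2.set_xlabel("cluster")
    ax2.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_depth_metrics(metrics: pd.DataFrame, out_path) -> None:
    """Saturation / genes / UMIs as functions of mean reads per cell."""
    panels = [
        ("sequencing_saturation", "sequencing saturation"),
        ("total_genes_detected", "total genes detected"),
        ("median_genes_per_cell", "median genes per cell"),
        ("median_umi_per_cell", "median UMIs per cell"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    for ax, (col, title) in zip(axes.ravel(), panels):
        for cond, grp in metrics.groupby("condition"):
            g = grp.sort_values("mean_reads_per_cell")
            ax.plot(g["mean_reads_per_cell"], g[col], marker="o", ms=3, label=cond)
        ax.set_xlabel("mean reads per cell")
        ax.set_title(title, fontsize=9)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_accuracy_curves(grid: pd.DataFrame, out_path, reference_line: float = 0.9) -> None:
    """Accuracy vs depth (cells fixed) and vs cell number, replicate spread."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    depth_arm = grid[grid["n_cells_target"] == 0]
    if not depth_arm.empty:
        med = depth_arm.groupby("depth_target")["accuracy"].median()
        ax1.plot(med.index, med.to_numpy(), "-o", ms=4)
        ax1.scatter(depth_arm["depth_target"], depth_arm["accuracy"], s=8, alpha=0.4)
    ax1.axhline(reference_line, ls="--", c="grey")
    ax1.set_xlabel("mean reads per cell")
    ax1.set_ylabel("accuracy")
    ax1.set_title("read-depth subsampling", fontsize=9)
    cell_arm = grid[grid["n_cells_target"] > 0]
    if not cell_arm.empty:
        med = cell_arm.groupby("n_cells_target")["accuracy"].median()
        ax2.plot(med.index, med.to_numpy(), "-o", ms=4)
        ax2.scatter(cell_arm["n_cells_target"], cell_arm["accuracy"], s=8, alpha=0.4)
    ax2.axhline(reference_line, ls="--", c="grey")
    ax2.set_xlabel("cell number")
    ax2.set_ylabel("accuracy")
    ax2.set_title("cell-number subsampling", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_accuracy_heatmap(grid: pd.DataFrame, out_path) -> pd.DataFrame:
    """Median accuracy per (depth, cells) tile; returns the tile table."""
    cell_arm = grid[grid["n_cells_target"] > 0]
    tiles = (
        cell_arm.groupby(["depth_target", "n_cells_target"])["accuracy"]
        .median()
        .reset_index()
    )
    pivot = tiles.pivot(index="depth_target", columns="n_cells_target", values="accuracy")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), [str(c) for c in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), [f"{d:.0f}" for d in pivot.index])
    ax.set_xlabel("cell number")
    ax.set_ylabel("mean reads per cell")
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            v = pivot.to_numpy()[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7, color="w")
    fig.colorbar(im, label="median accuracy")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return tiles


def make_report(results_dir, out_dir=None) -> dict:
    """Render every figure for which a results table exists.

    Expects ``benchmark_grid.tsv``, ``depth_metrics.tsv`` and/or
    ``tsne.tsv`` under ``results_dir``; raises if none are present and
    lists the missing panels otherwise.
    """
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir is not None else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    produced, missing = {}, []

    grid_path = results_dir / GRID_TSV
    if grid_path.exists():
        grid = pd.read_csv(grid_path, sep="\t")
        plot_accuracy_curves(grid, out_dir / "accuracy_curves.png")
        tiles = plot_accuracy_heatmap(grid, out_dir / "accuracy_heatmap.png")
        tiles.to_csv(out_dir / "accuracy_tiles.tsv", sep="\t", index=False)
        produced["accuracy_curves"] = out_dir / "accuracy_curves.png"
        produced["accuracy_heatmap"] = out_dir / "accuracy_heatmap.png"
    else:
        missing.append(str(grid_path))

    depth_path = results_dir / DEPTH_TSV
    if depth_path.exists():
        metrics = pd.read_csv(depth_path, sep="\t")
        plot_depth_metrics(metrics, out_dir / "depth_metrics.png")
        produced["depth_metrics"] = out_dir / "depth_metrics.png"
    else:
        missing.append(str(depth_path))

    tsne_path = results_dir / TSNE_TSV
    if tsne_path.exists():
        tsne = pd.read_csv(tsne_path, sep="\t")
        plot_tsne_frequency(tsne, out_dir / "tsne_frequency.png")
        produced["tsne_frequency"] = out_dir / "tsne_frequency.png"
    else:
        missing.append(str(tsne_path))

    if not produced:
        raise FileNotFoundError(
            "no results tables found; expected any of: " + ", ".join(missing)
        )
    return {"produced": produced, "missing": missing}
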