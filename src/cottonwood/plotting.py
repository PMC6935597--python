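"""Figures: joint-AFS heatmaps and Manhattan-style Fst tracks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .afs import AFSGrid

__all__ = ["plot_afs_heatmap", "plot_manhattan"]


def plot_afs_heatmap(grid: AFSGrid, path, log_scale: bool = True) -> None:
    """Heatmap of a joint spectrum; masked cells are blanked white."""
    data = grid.counts.astype(float).copy()
    data[grid.mask] = np.nan
    if log_scale and not grid.normalized:
        with np.errstate(divide="ignore"):
            data = np.log10(data + 1)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(data.T, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xlabel(f"derived allele count, {grid.pool_a}")
    ax.set_ylabel(f"derived allele count, {grid.pool_b}")
    label = "normalized frequency" if grid.normalized else "log10(SNPs + 1)"
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_manhattan(track: pd.DataFrame, path, highlight=None) -> None:
    """Per-SNP Fst against cumulative genome position, colored by chromosome."""
    t = track.dropna(subset=["fst"]).sort_values(["chrom", "pos"])
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(t.groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["fst"], s=4, color=["#33537d", "#7d9cc0"][i % 2])
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max()
    if highlight is not None:
        for _, row in highlight.iterrows():
            ax.axvspan(row["start"], row["end"], color="red", alpha=0.2)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("Fst")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
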