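"""Scatter/histogram exports for distance and divergence results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .spatial import DistanceDistribution


def plot_distance_distribution(
    dist: DistanceDistribution, path: str | Path, title: str = ""
) -> None:
    """Bar plot of a normalized PM-distance distribution."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    widths = np.diff(dist.bin_edges)
    ax.bar(dist.bin_edges[:-1], dist.probabilities, width=widths, align="edge",
           edgecolor="black", linewidth=0.4)
    ax.set_xlabel("normalized distance to PM, d")
    ax.set_ylabel("probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_divergence_scatter(div_table: pd.DataFrame, path: str | Path) -> None:
    """Per-class Bhattacharyya-distance scatter (one column per cell/class)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    finite = div_table[np.isfinite(div_table["bd"])]
    for i, (cls, sub) in enumerate(finite.groupby("placement_class")):
        x = i + 0.08 * np.random.default_rng(0).standard_normal(len(sub))
        ax.scatter(x, sub["bd"], s=8, alpha=0.6, label=f"class {cls}")
    ax.set_xticks(range(finite["placement_class"].nunique()))
    ax.set_xticklabels(sorted(finite["placement_class"].unique()))
    ax.set_xlabel("null-model class")
    ax.set_ylabel("Bhattacharyya distance")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
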