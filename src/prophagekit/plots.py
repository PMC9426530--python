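"""Plain matplotlib exports of the main results (values only, no styling
guarantees): bootstrap p-value boxplots, size-abundance scatter, and a
log-bias heatmap."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["bootstrap_boxplot", "size_abundance_plot", "bias_heatmap"]


def bootstrap_boxplot(results: Sequence, path: str | Path) -> None:
    """Boxplot of per-genus bootstrap p-values with the 0.05 line."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(results)), 4))
    ax.boxplot([r.p_values for r in results],
               tick_labels=[r.genus for r in results])
    ax.axhline(0.05, linestyle=":", color="tab:blue")
    ax.set_ylabel("Wilcoxon p-value")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def size_abundance_plot(bins, path: str | Path) -> None:
    """Total and mean prophage counts per genome-size bin."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    ax1.plot(bins["bin_mb"], bins["total"], marker="o", color="tab:green",
             label="all")
    ax1.plot(bins["bin_mb"], bins["total_long"], marker="s", color="tab:brown",
             label=">= 30 kb")
    ax1.set_xlabel("genome size (Mb)")
    ax1.set_ylabel("total prophages")
    ax1.legend()
    ax2.plot(bins["bin_mb"], bins["mean"], marker="o", color="tab:green")
    ax2.plot(bins["bin_mb"], bins["mean_long"], marker="s", color="tab:brown")
    ax2.set_xlabel("genome size (Mb)")
    ax2.set_ylabel("mean prophages per genome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bias_heatmap(matrix, path: str | Path) -> None:
    """Heatmap of a log-bias profile matrix (rows = sequences)."""
    fig, ax = plt.subplots(
        figsize=(max(4, 0.12 * matrix.shape[1]), max(3, 0.25 * matrix.shape[0])))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="coolwarm")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="log bias")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
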