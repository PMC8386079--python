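"""Plain figure export: proportion heatmaps and per-type error boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def proportion_heatmap(proportions: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Heatmap of a samples × cell-types proportion matrix, saved as PNG."""
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * proportions.shape[1], 1.0 + 0.35 * proportions.shape[0])
    )
    im = ax.imshow(proportions.to_numpy(), cmap="viridis", vmin=0.0, aspect="auto")
    ax.set_xticks(range(proportions.shape[1]), [str(c) for c in proportions.columns],
                  rotation=45, ha="right")
    ax.set_yticks(range(proportions.shape[0]), [str(i) for i in proportions.index])
    fig.colorbar(im, ax=ax, label="proportion")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def error_boxplot(pred: pd.DataFrame, truth: pd.DataFrame, path: str | Path) -> None:
    """Boxplot of per-cell-type absolute prediction errors, saved as PNG."""
    truth = truth.loc[pred.index, pred.columns]
    err = (pred - truth).abs()
    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * err.shape[1], 3.5))
    ax.boxplot([err[c].to_numpy() for c in err.columns],
               tick_labels=[str(c) for c in err.columns])
    ax.set_ylabel("|predicted - true|")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
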