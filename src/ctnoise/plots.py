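"""Cohort-level figures: metric box plots and correlation heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["boxplot_metrics", "heatmap_correlation"]


def boxplot_metrics(
    table: pd.DataFrame,
    path: str | Path,
    threshold_hu: float | None = None,
    title: str = "Global noise by metric",
) -> Path:
    """Box plots of exam-level GN per metric, with the CMS threshold line."""
    fig, ax = plt.subplots(figsize=(8, 5))
    data = [table[c].dropna().to_numpy() for c in table.columns]
    ax.boxplot(data, tick_labels=[str(c) for c in table.columns])
    if threshold_hu is not None:
        ax.axhline(threshold_hu, linestyle=":", color="k", label=f"CMS threshold ({threshold_hu} HU)")
        ax.legend()
    ax.set_ylabel("Global noise (HU)")
    ax.set_title(title)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def heatmap_correlation(r: pd.DataFrame, path: str | Path, title: str = "Pearson r") -> Path:
    """Heatmap of the metric correlation matrix with annotated r values."""
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    m = r.to_numpy(dtype=float)
    im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r.columns)), [str(c) for c in r.columns], rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), [str(c) for c in r.index])
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            txt = "n/a" if np.isnan(m[i, j]) else f"{m[i, j]:.2f}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
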