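"""Figure helpers: bubble plots of gene abundance and clustered heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .abundance import AbundanceMatrix

__all__ = ["bubble_plot", "clustermap"]


def bubble_plot(matrix: AbundanceMatrix, ax=None, max_size: float = 600.0,
                scale: float = 1.0):
    """Gene x sample bubble chart; bubble area is proportional to value."""
    df = matrix.df * scale
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.5 * df.shape[1], 1 + 0.35 * df.shape[0]))
    vmax = df.to_numpy().max() or 1.0
    for i, gene in enumerate(df.index):
        for j, sample in enumerate(df.columns):
            v = df.iloc[i, j]
            if v > 0:
                ax.scatter(j, i, s=max_size * v / vmax, c="tab:blue",
                           alpha=0.7, edgecolors="none")
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=90)
    ax.set_yticks(range(df.shape[0]), df.index)
    ax.set_xlim(-0.5, df.shape[1] - 0.5)
    ax.set_ylim(df.shape[0] - 0.5, -0.5)
    ax.set_title(f"{matrix.assay.value.lower()} abundance "
                 f"({matrix.normalization.value.lower()} normalized)")
    return ax


def clustermap(df, row_cluster: bool = True, col_cluster: bool = True, **kwargs):
    """Seaborn clustermap with the package's fixed metric/linkage
    (Euclidean distance, Ward linkage)."""
    kwargs.setdefault("cmap", "vlag")
    kwargs.setdefault("center", 0)
    return sns.clustermap(df, method="ward", metric="euclidean",
                          row_cluster=row_cluster, col_cluster=col_cluster,
                          **kwargs)
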