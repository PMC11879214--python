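"""Diagnostic scatter plots: windows in ESP-PCA space and in covariate space."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cover import CoverGeometry
from .esp import ESPMatrix
from .regions import project_windows_2d

__all__ = ["plot_window_projection", "plot_region_midpoints"]


def plot_window_projection(esp: ESPMatrix, labels, path: str | Path) -> None:
    """Windows projected on the first two principal axes of the standardized
    ESP, coloured by cluster."""
    Y = project_windows_2d(esp)
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(Y[:, 0], Y[:, 1], c=np.asarray(labels), cmap="tab10", s=35)
    ax.set_xlabel("PC1 of window effect sizes")
    ax.set_ylabel("PC2 of window effect sizes")
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_region_midpoints(cover: CoverGeometry, labels, path: str | Path) -> None:
    """Window midpoints in (the first two) covariate dimensions, coloured by
    cluster — the fuzzy region map."""
    mids = cover.midpoints()
    fig, ax = plt.subplots(figsize=(5, 4))
    x = mids[:, 0]
    y = mids[:, 1] if mids.shape[1] > 1 else np.zeros_like(x)
    sc = ax.scatter(x, y, c=np.asarray(labels), cmap="tab10", s=35)
    ax.set_xlabel(cover.continuous_cols[0])
    if mids.shape[1] > 1:
        ax.set_ylabel(cover.continuous_cols[1])
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
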