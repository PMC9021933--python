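"""Minimal plotting helpers (matplotlib, no display assumptions)."""

from __future__ import annotations

import numpy as np

from .morphospace import Morphospace, TopologyComparison


def plot_topology_matrix(comparison: TopologyComparison, ax=None):
    """Heatmap of the cross-approach Pearson correlation matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    m = comparison.matrix
    im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdYlBu_r")
    ax.set_xticks(range(len(comparison.labels)), comparison.labels, rotation=90)
    ax.set_yticks(range(len(comparison.labels)), comparison.labels)
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            ax.text(j, i, f"{m[i, j]:.2f}", ha="center", va="center", fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax


def plot_morphospace(space: Morphospace, labels=None, axes=(1, 2), ax=None):
    """Scatter of individuals on two retained axes, optionally by group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    i, j = axes[0] - 1, axes[1] - 1
    if labels is None:
        ax.scatter(space.scores[:, i], space.scores[:, j], s=12)
    else:
        labels = np.asarray(labels, dtype=object)
        for g in dict.fromkeys(labels):
            sel = labels == g
            ax.scatter(space.scores[sel, i], space.scores[sel, j], s=12, label=str(g))
        ax.legend(fontsize=8)
    ax.set_xlabel(f"PC{axes[0]} ({space.explained[i]:.0%})")
    ax.set_ylabel(f"PC{axes[1]} ({space.explained[j]:.0%})")
    ax.set_title(space.method_tag)
    return ax
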