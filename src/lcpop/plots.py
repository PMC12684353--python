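"""Small plotting helpers for PCA, admixture and scan outputs."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_pca(pca, demes=None, axes=(0, 1), ax=None, path=None):
    """Scatter of two principal axes, colored by deme when given."""
    ax = ax or plt.figure(figsize=(5, 4)).add_subplot()
    a, b = axes
    if demes is None:
        ax.scatter(pca.scores[:, a], pca.scores[:, b], s=12)
    else:
        demes = np.asarray(demes)
        for d in np.unique(demes):
            m = demes == d
            ax.scatter(pca.scores[m, a], pca.scores[m, b], s=12, label=str(d))
        ax.legend(title="deme", fontsize=8)
    ax.set_xlabel(f"PC{a + 1} ({100 * pca.var_explained[a]:.2f}%)")
    ax.set_ylabel(f"PC{b + 1} ({100 * pca.var_explained[b]:.2f}%)")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_admixture(Q, demes=None, ax=None, path=None):
    """Stacked-bar admixture proportions, individuals grouped by deme."""
    Q = np.asarray(Q)
    order = np.argsort(demes) if demes is not None else np.arange(len(Q))
    ax = ax or plt.figure(figsize=(8, 2.5)).add_subplot()
    bottom = np.zeros(len(Q))
    for k in range(Q.shape[1]):
        ax.bar(np.arange(len(Q)), Q[order, k], bottom=bottom, width=1.0)
        bottom += Q[order, k]
    ax.set_xlim(-0.5, len(Q) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_mds_scan(coords, windows, axis=0, ax=None, path=None):
    """Per-window MDS coordinate along the genome (SV scan view)."""
    ax = ax or plt.figure(figsize=(8, 2.5)).add_subplot()
    x = [w.first_pos for w in windows]
    ax.scatter(x, np.asarray(coords)[:, axis], s=10, c=np.abs(np.asarray(coords)[:, axis]))
    ax.set_xlabel("window start (bp)")
    ax.set_ylabel(f"MDS axis {axis + 1}")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
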