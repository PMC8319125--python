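"""Figure helpers: z-score heatmaps, ROC curves, UMAP scatter, phasor plots.

Thin matplotlib wrappers for the standard OMI figures; each function
returns the Figure and optionally saves it (PNG/SVG by file suffix).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import leaves_list

from .multivariate import ClassifierReport, DendrogramResult, ZScoreTable

__all__ = ["zscore_heatmap", "roc_figure", "umap_figure", "phasor_figure"]


def _save(fig, path):
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def zscore_heatmap(z: ZScoreTable, dendro: DendrogramResult | None = None,
                   path: str | Path | None = None):
    """Variables × conditions heatmap, leaves ordered by the dendrograms."""
    values = z.values
    if dendro is not None:
        values = values.iloc[leaves_list(dendro.variable_linkage),
                             leaves_list(dendro.condition_linkage)]
    fig, ax = plt.subplots(figsize=(0.6 * values.shape[1] + 3, 6))
    im = ax.imshow(values.to_numpy(), cmap="RdBu_r", aspect="auto",
                   vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=90)
    ax.set_yticks(range(values.shape[0]), values.index)
    fig.colorbar(im, ax=ax, label="z-score")
    return _save(fig, path)


def roc_figure(reports: list[ClassifierReport],
               path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        ax.plot(rep.roc_fpr, rep.roc_tpr,
                label=f"{rep.subset} (AUC {rep.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    return _save(fig, path)


def umap_figure(coords: np.ndarray, labels, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 5))
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(coords[sel, 0], coords[sel, 1], s=4, label=str(lab),
                   alpha=0.6)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(markerscale=3)
    return _save(fig, path)


def phasor_figure(g: np.ndarray, s: np.ndarray,
                  path: str | Path | None = None, bins: int = 128):
    """2D histogram of phasor points with the universal semicircle."""
    g, s = np.asarray(g).ravel(), np.asarray(s).ravel()
    ok = np.isfinite(g) & np.isfinite(s)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.hist2d(g[ok], s[ok], bins=bins, range=[[0, 1], [0, 0.65]],
              cmap="viridis", cmin=1)
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "w--", lw=1)
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    return _save(fig, path)
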