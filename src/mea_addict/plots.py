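"""Figure exports: PC-plane centroid plot and parameter heat-map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bursts import PARAMETERS
from .recording import AFTER, BEFORE

__all__ = ["plot_pca_centroids", "plot_parameter_heatmap"]


def plot_pca_centroids(scores: pd.DataFrame, path: str | Path, evr=None) -> Path:
    """Before/after centroid trajectories per compound on the PC1-PC2 plane.

    Circles: before chronic exposure; squares: after.  One panel per
    compound, centroids per concentration joined by a line.
    """
    compounds = sorted(scores["compound"].unique())
    n = len(compounds)
    ncol = min(5, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    for ax, comp in zip(axes.ravel(), compounds):
        sub = scores[scores["compound"] == comp]
        for phase, marker in ((BEFORE, "o"), (AFTER, "s")):
            cent = (
                sub[sub["phase"] == phase]
                .groupby("concentration")[["PC1", "PC2"]]
                .mean()
                .sort_index()
            )
            ax.plot(cent["PC1"], cent["PC2"], marker=marker, ms=5, lw=1, label=phase)
        ax.set_title(comp, fontsize=9)
        ax.axhline(0, color="0.8", lw=0.5)
        ax.axvline(0, color="0.8", lw=0.5)
    xlab, ylab = "PC1", "PC2"
    if evr is not None and len(evr) >= 2:
        xlab += f" ({evr[0]:.1f}%)"
        ylab += f" ({evr[1]:.1f}%)"
    for ax in axes[-1]:
        ax.set_xlabel(xlab, fontsize=8)
    for row in axes:
        row[0].set_ylabel(ylab, fontsize=8)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_parameter_heatmap(summary: pd.DataFrame, phase: str, path: str | Path) -> Path:
    """Heat-map of normalized group means (compound x dose step rows,
    parameter columns) with significance asterisks from Dunnett's test."""
    sub = summary[(summary["phase"] == phase) & (summary["concentration"] > 0)].copy()
    sub["row"] = sub["compound"] + " @" + sub["concentration"].map("{:g}".format)
    piv = sub.pivot_table(index="row", columns="parameter", values="mean", observed=True)
    piv = piv[[p for p in PARAMETERS if p in piv.columns]]
    sig = sub.pivot_table(
        index="row", columns="parameter", values="significant", aggfunc="first", observed=True
    ).reindex(index=piv.index, columns=piv.columns)
    fig, ax = plt.subplots(figsize=(0.65 * len(piv.columns) + 2, 0.22 * len(piv) + 2))
    im = ax.imshow(piv.to_numpy(), aspect="auto", cmap="coolwarm", vmin=0, vmax=200)
    ax.set_xticks(range(len(piv.columns)), piv.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(piv)), piv.index, fontsize=6)
    for i in range(piv.shape[0]):
        for j in range(piv.shape[1]):
            if bool(sig.iloc[i, j]):
                ax.text(j, i, "*", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="% of vehicle")
    ax.set_title(f"parameter means, {phase}", fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
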