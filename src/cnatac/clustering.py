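"""Clonal structure: Ward clustering of karyotypes and the karyogram plot.

Cells are clustered on the Euclidean distance between their raw {0,1,2}
state rows with Ward linkage — cells sharing a genome-wide CNA profile form
karyotype clones.  The flat cut is user-supplied (``n_clusters``); the
dendrogram is kept for manual inspection of nested sub-clones.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin

from .calling import Karyotype

__all__ = ["KaryotypeClusterer", "cluster_karyotypes", "plot_karyogram"]

_STATE_COLORS = ["#3b4cc0", "#d8d8d8", "#b40426"]  # loss, normal, gain


class KaryotypeClusterer(BaseEstimator, ClusterMixin):
    """Agglomerative Ward clustering of per-cell copy-number profiles.

    Parameters
    ----------
    n_clusters : number of flat clusters to cut from the Ward dendrogram.

    Fitted attributes
    -----------------
    labels_ : clone label per cell, contiguous integers from 1, numbered in
        order of first appearance (deterministic given input order).
    linkage_ : the scipy linkage matrix (merge topology and heights).
    leaf_order_ : dendrogram leaf order, used to sort heatmap rows.
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 cells")
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the {X.shape[0]} cells"
            )
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        self.linkage_ = hierarchy.linkage(X, method="ward")
        raw = hierarchy.fcluster(self.linkage_, self.n_clusters, criterion="maxclust")
        relabel: dict[int, int] = {}
        labels = np.empty_like(raw)
        for i, r in enumerate(raw):
            labels[i] = relabel.setdefault(r, len(relabel) + 1)
        self.labels_ = labels
        self.leaf_order_ = hierarchy.leaves_list(self.linkage_)
        self.n_features_in_ = X.shape[1]
        return self


def cluster_karyotypes(karyotype: Karyotype, n_clusters: int) -> pd.DataFrame:
    """Cluster cells by karyotype; returns a (cell_id, clone) table."""
    model = KaryotypeClusterer(n_clusters=n_clusters).fit(karyotype.states)
    return pd.DataFrame(
        {"cell_id": list(karyotype.cell_ids), "clone": model.labels_}
    )


def plot_karyogram(
    karyotype: Karyotype,
    path: str | Path,
    chrom_labels: np.ndarray | None = None,
    clones: pd.DataFrame | None = None,
) -> None:
    """Render the cells x bins heatmap (rows = cells, columns = genome).

    Rows are ordered by the Ward dendrogram; chromosome boundaries are drawn
    when per-bin chromosome labels are given, and a clone annotation bar is
    added when a clone table is supplied.  Loss is blue, normal gray, gain
    red.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    states = karyotype.states
    if states.size == 0:
        raise ValueError("empty karyotype matrix")
    if states.shape[0] >= 2:
        order = KaryotypeClusterer(n_clusters=1).fit(states).leaf_order_
    else:
        order = np.arange(states.shape[0])

    with_bar = clones is not None
    fig, axes = plt.subplots(
        1,
        2 if with_bar else 1,
        figsize=(10, max(2.5, 0.02 * states.shape[0] + 1.5)),
        gridspec_kw={"width_ratios": [1, 40]} if with_bar else None,
        squeeze=False,
    )
    ax = axes[0, -1]
    ax.imshow(
        states[order],
        aspect="auto",
        interpolation="nearest",
        cmap=ListedColormap(_STATE_COLORS),
        vmin=0,
        vmax=2,
    )
    if chrom_labels is not None:
        chrom_labels = np.asarray(chrom_labels)
        bounds = np.flatnonzero(chrom_labels[1:] != chrom_labels[:-1]) + 1
        for b in bounds:
            ax.axvline(b - 0.5, color="black", lw=0.8)
        ticks = []
        start = 0
        for b in list(bounds) + [len(chrom_labels)]:
            ticks.append((start + b - 1) / 2)
            start = b
        ax.set_xticks(ticks)
        ax.set_xticklabels(list(dict.fromkeys(chrom_labels)), fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("genomic bins")
    ax.set_ylabel(f"{states.shape[0]} cells")
    if with_bar:
        lut = dict(zip(clones["cell_id"], clones["clone"]))
        labels = np.array([lut[c] for c in karyotype.cell_ids])[order]
        bar = axes[0, 0]
        bar.imshow(
            labels[:, None], aspect="auto", interpolation="nearest", cmap="tab10"
        )
        bar.set_xticks([])
        bar.set_yticks([])
        bar.set_title("clone", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
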