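"""Binary occupancy annotation and co-localization clustering.

A peak x feature AnnotationMatrix holds 1 where a peak overlaps any
interval of a feature set (promoters, enhancer marks, other ChIP peaks...).
Unsupervised agglomerative clustering with Jaccard distance and average
linkage separates peaks into co-localization classes — e.g. the class of
PRC2 peaks that coincide with H3K4me1 but carry little H3K27me3 (poised
enhancers) versus the class coinciding with promoters and retained
H3K27me3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from .intervals import overlaps_any

log = logging.getLogger(__name__)


def annotate_peaks(peaks: pd.DataFrame, features: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Binary peaks x features occupancy matrix.

    cell(i, j) = 1 iff peak i overlaps >= 1 interval of feature j by >= 1
    bp.  An empty feature set yields an all-zero column (with a warning).
    Row index is the peak name (or ``peak_<i>`` when absent).
    """
    names = list(features)
    if len(names) != len(set(names)):
        raise ValueError("feature names must be unique")
    if "name" in peaks.columns:
        index = pd.Index(peaks["name"].astype(str), name="peak")
    else:
        index = pd.Index([f"peak_{i}" for i in range(len(peaks))], name="peak")
    if index.duplicated().any():
        raise ValueError("peak names must be unique for annotation")
    cols = {}
    for feat, intervals in features.items():
        if len(intervals) == 0:
            log.warning("feature %r has no intervals; all-zero column", feat)
            cols[feat] = np.zeros(len(peaks), dtype=np.int8)
        else:
            cols[feat] = overlaps_any(peaks, intervals).astype(np.int8)
    return pd.DataFrame(cols, index=index)


def cluster_binary(matrix: pd.DataFrame, k: int = 5, min_cluster_frac: float = 0.01) -> pd.Series:
    """Agglomerative (Jaccard distance, average linkage) clustering of
    binary rows into ``k`` co-localization classes.

    The dendrogram is cut so that ``k`` clusters of meaningful size emerge:
    starting from a ``maxclust`` cut at k, the cut is deepened while fewer
    than k clusters reach ``min_cluster_frac`` of the rows (minimum 2) —
    rare outlier rows otherwise capture whole cluster slots.  Rows left in
    sub-threshold clusters are assigned to the core cluster with the
    smallest mean Jaccard distance.  The Jaccard distance of two all-zero
    rows is 0 (scipy's convention), so fully unannotated peaks form their
    own natural cluster.  Labels are renumbered 1..k in order of first
    appearance, making the assignment deterministic given input row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = matrix.shape[0]
    if n == 0:
        raise ValueError("empty annotation matrix")
    X = matrix.to_numpy(dtype=bool)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct rows ({n_distinct})")
    if k == 1 or n == 1:
        labels = np.ones(n, dtype=int)
    else:
        # canonical row order: linkage tie-breaking is order-dependent, so
        # cluster in pattern-lexicographic order to make the assignment
        # invariant to input row permutation (identical patterns always
        # share a cluster: their Jaccard distance is 0)
        canon = np.lexsort(X.T[::-1])
        X = X[canon]
        dist = pdist(X, metric="jaccard")
        Z = average(dist)
        min_size = max(2, int(np.ceil(min_cluster_frac * n)))
        labels = None
        for t in range(k, min(4 * k, n) + 1):
            cand = fcluster(Z, t=t, criterion="maxclust")
            ids, sizes = np.unique(cand, return_counts=True)
            big = ids[sizes >= min_size]
            if len(big) >= k or labels is None:
                labels = cand
            if len(big) >= k:
                break
        ids, sizes = np.unique(labels, return_counts=True)
        order = np.lexsort((ids, -sizes))
        core_ids = set(ids[order][:k][sizes[order][:k] >= 1])
        # demote everything outside the k largest clusters, then reattach
        outlier_rows = np.flatnonzero(~np.isin(labels, list(core_ids)))
        if len(outlier_rows):
            from scipy.spatial.distance import cdist

            core_list = sorted(core_ids)
            D = cdist(X[outlier_rows], X, metric="jaccard")
            mean_dist = np.column_stack(
                [D[:, labels == cid].mean(axis=1) for cid in core_list]
            )
            nearest = np.argmin(mean_dist, axis=1)
            labels = labels.copy()
            labels[outlier_rows] = np.array(core_list)[nearest]
        # map labels back from canonical to input order
        unsorted = np.empty(n, dtype=int)
        unsorted[canon] = labels
        labels = unsorted
    # renumber by first appearance
    remap: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return pd.Series(out, index=matrix.index, name="cluster")


def cluster_sizes(assignment: pd.Series) -> pd.Series:
    return assignment.value_counts().sort_index().rename("n_peaks")


def heatmap_order(matrix: pd.DataFrame, assignment: pd.Series) -> pd.Index:
    """Row order for the black/white occupancy heatmap.

    Rows are grouped by cluster and ordered within a cluster by row sum
    descending, ties by row id.  Cluster blocks are ordered by size
    descending, ties by their lexicographically smallest row id, so the
    rendered matrix is invariant to input row permutation (clusters only
    get relabelled).
    """
    if not assignment.index.equals(matrix.index):
        assignment = assignment.reindex(matrix.index)
    if assignment.isna().any():
        raise ValueError("assignment does not cover all matrix rows")
    row_sums = matrix.sum(axis=1)
    blocks = []
    for lab in assignment.unique():
        ids = matrix.index[assignment.to_numpy() == lab]
        ordered = sorted(ids, key=lambda i: (-row_sums[i], str(i)))
        blocks.append((-len(ids), min(str(i) for i in ids), ordered))
    blocks.sort(key=lambda b: (b[0], b[1]))
    order = [i for _, _, ids in blocks for i in ids]
    return pd.Index(order, name=matrix.index.name)


def render_heatmap(matrix: pd.DataFrame, assignment: pd.Series, path=None):
    """Render the ordered binary matrix as a black/white raster.

    Returns the matplotlib Figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = heatmap_order(matrix, assignment)
    M = matrix.loc[order].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(2, 0.6 * matrix.shape[1]), 6))
    ax.imshow(1 - M, aspect="auto", interpolation="nearest", cmap="gray", vmin=0, vmax=1)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} peaks")
    sizes = cluster_sizes(assignment.loc[order].reset_index(drop=True))
    ax.set_title("co-localization clusters: " + ", ".join(f"N={v}" for v in sizes.to_numpy()), fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
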