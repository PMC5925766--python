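"""Distances, agglomerative clustering, tree cutting and silhouette-based
selection of the number of clusters.

The row (or column) dendrogram of a cluster heatmap is produced by
agglomerative hierarchical clustering of pairwise distances; the defaults —
Euclidean distance with average (UPGMA) linkage — match common practice for
omics matrices. When the user does not fix the number of clusters used to
color the dendrogram branches, :func:`find_k` searches k = 2..10 and keeps
the cut with the highest average silhouette coefficient.

Missing values are handled at the distance stage with pairwise-complete
columns: each pair of rows is compared over the columns both observe, and
euclidean/manhattan sums are rescaled by ``n_cols / n_jointly_observed`` so
distances remain comparable across pairs with different amounts of overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .matrix_io import DataMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "ClusteringError",
    "METRICS",
    "LINKAGES",
    "compute_distance",
    "agglomerate",
    "cut_tree",
    "mean_silhouette",
    "find_k",
]

METRICS = ("euclidean", "manhattan", "maximum", "pearson")
LINKAGES = ("single", "complete", "average", "ward")


class ClusteringError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with labels."""

    d: np.ndarray
    labels: list[str]
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ClusteringError("distance matrix must be square")
        if len(self.labels) != n:
            raise ClusteringError("label count must match matrix size")
        if not np.allclose(self.d, self.d.T, equal_nan=False):
            raise ClusteringError("distance matrix must be symmetric")
        if np.any(np.diagonal(self.d) != 0):
            raise ClusteringError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ClusteringError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``linkage_matrix`` is the standard (n-1) x 4 encoding: each row is
    (left node id, right node id, merge height, cluster size), with leaves
    numbered 0..n-1 and internal nodes n..2n-2 in merge order.
    ``leaf_order`` is the current display permutation; seriation replaces it
    with a branch-flip-equivalent permutation.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    leaf_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.linkage_matrix = np.asarray(self.linkage_matrix, dtype=float)
        n = self.n_leaves
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ClusteringError("linkage matrix must be (n-1) x 4")
        if self.leaf_order is None:
            self.leaf_order = hierarchy.leaves_list(self.linkage_matrix).astype(int)
        else:
            self.leaf_order = np.asarray(self.leaf_order, dtype=int)
            if sorted(self.leaf_order) != list(range(n)):
                raise ClusteringError("leaf_order must be a permutation of 0..n-1")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """(left id, right id, height) triples in merge order."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def children(self) -> dict[int, tuple[int, int]]:
        """Internal node id -> (left child id, right child id)."""
        n = self.n_leaves
        return {n + i: (int(a), int(b))
                for i, (a, b, _, _) in enumerate(self.linkage_matrix)}

    def leaves_under(self) -> dict[int, list[int]]:
        """Node id -> leaf ids in its subtree (leaves map to themselves)."""
        n = self.n_leaves
        out: dict[int, list[int]] = {i: [i] for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.linkage_matrix):
            out[n + i] = out[int(a)] + out[int(b)]
        return out

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def with_leaf_order(self, order) -> "Dendrogram":
        return Dendrogram(self.linkage_matrix.copy(), list(self.labels),
                          np.asarray(order, dtype=int))


@dataclass
class ClusterAssignment:
    """A flat k-cluster partition of the leaves, optionally with its score.

    Cluster ids are 0..k-1, numbered by first appearance along the
    dendrogram's leaf order, so cluster 0 is always the leftmost on a plot.
    """

    k: int
    labels_by_leaf: np.ndarray
    mean_silhouette: float | None = None

    def __post_init__(self) -> None:
        self.labels_by_leaf = np.asarray(self.labels_by_leaf, dtype=int)
        ids = np.unique(self.labels_by_leaf)
        if len(ids) != self.k:
            raise ClusteringError(
                f"expected {self.k} distinct cluster ids, found {len(ids)}")


def _pairwise_complete(values: np.ndarray, metric: str,
                       labels: list[str]) -> np.ndarray:
    """Pairwise distances between rows when some cells are missing."""
    n, p = values.shape
    finite = ~np.isnan(values)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = finite[i] & finite[j]
            nj = int(joint.sum())
            if nj == 0:
                raise ClusteringError(
                    f"rows {labels[i]!r} and {labels[j]!r} share no observed columns")
            xi, xj = values[i, joint], values[j, joint]
            diff = xi - xj
            if metric == "euclidean":
                v = np.sqrt(np.sum(diff ** 2) * (p / nj))
            elif metric == "manhattan":
                v = np.sum(np.abs(diff)) * (p / nj)
            elif metric == "maximum":
                v = np.max(np.abs(diff))
            else:  # pearson
                if nj < 2 or xi.std() == 0 or xj.std() == 0:
                    raise ClusteringError(
                        f"pearson dissimilarity undefined for rows "
                        f"{labels[i]!r} and {labels[j]!r}")
                v = 1.0 - np.corrcoef(xi, xj)[0, 1]
            d[i, j] = d[j, i] = max(v, 0.0)
    return d


def compute_distance(m: DataMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between the rows of ``m``.

    Metrics: ``euclidean``, ``manhattan``, ``maximum`` (Chebyshev) and
    ``pearson`` (1 - Pearson correlation, clipped at 0).
    """
    if metric not in METRICS:
        raise ClusteringError(f"unknown metric {metric!r}; choose from {METRICS}")
    if m.n_rows < 2:
        raise ClusteringError("need at least 2 rows to compute distances")
    if m.missing_mask.any():
        d = _pairwise_complete(m.values, metric, m.row_labels)
    elif metric == "pearson":
        sd = m.values.std(axis=1)
        if np.any(sd == 0):
            i = int(np.argmax(sd == 0))
            raise ClusteringError(
                f"pearson dissimilarity undefined for constant row {m.row_labels[i]!r}")
        d = np.clip(1.0 - np.corrcoef(m.values), 0.0, None)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
    else:
        scipy_name = {"euclidean": "euclidean", "manhattan": "cityblock",
                      "maximum": "chebyshev"}[metric]
        d = squareform(pdist(m.values, metric=scipy_name))
    return DistanceMatrix(d, list(m.row_labels), metric)


def agglomerate(d: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix into a dendrogram.

    Linkages: single (minimum), complete (maximum), average (UPGMA) and
    ward (Ward-D2, the squared-distance variant). Merge heights are
    monotone non-decreasing for all four.
    """
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if d.n < 2:
        raise ClusteringError("need at least 2 items to cluster")
    condensed = squareform(d.d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(Z, list(d.labels))


def cut_tree(t: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into k clusters by removing the k-1 highest merges.

    Cluster ids are renumbered by first appearance along ``t.leaf_order``.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ClusteringError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(t.linkage_matrix, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    for leaf in t.leaf_order:
        remap.setdefault(int(raw[leaf]), len(remap))
    labels = np.array([remap[int(c)] for c in raw], dtype=int)
    return ClusterAssignment(k=k, labels_by_leaf=labels)


def mean_silhouette(d: DistanceMatrix, a: ClusterAssignment) -> float:
    """Average silhouette coefficient of a partition under distances ``d``.

    For each point, s = (b - a) / max(a, b) with a = mean distance to its
    own cluster (excluding itself) and b = the smallest mean distance to
    another cluster; members of singleton clusters contribute s = 0.
    """
    if a.k < 2:
        raise ClusteringError("silhouette requires k >= 2")
    labels = a.labels_by_leaf
    n = d.n
    if len(labels) != n:
        raise ClusteringError("assignment length must match distance matrix")
    ids = np.unique(labels)
    # mean distance from every point to every cluster
    sums = np.stack([d.d[:, labels == c].sum(axis=1) for c in ids], axis=1)
    sizes = np.array([(labels == c).sum() for c in ids])
    s = np.zeros(n)
    for i in range(n):
        ci = np.searchsorted(ids, labels[i])
        if sizes[ci] == 1:
            continue
        a_i = sums[i, ci] / (sizes[ci] - 1)
        other = [sums[i, c] / sizes[c] for c in range(len(ids)) if c != ci]
        b_i = min(other)
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    return float(s.mean())


def find_k(d: DistanceMatrix, t: Dendrogram, k_min: int = 2,
           k_max: int = 10) -> ClusterAssignment:
    """Pick the tree cut (k = k_min..k_max) with the highest mean silhouette.

    Only cuts of the already-built dendrogram are scored — the search colors
    branches of one tree rather than re-clustering per k. ``k_max`` is
    clipped to n-1; ties go to the smallest k.
    """
    n = t.n_leaves
    if n < 3:
        raise ClusteringError("find_k needs at least 3 leaves")
    k_max = min(k_max, n - 1)
    if not 2 <= k_min <= k_max:
        raise ClusteringError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    best: ClusterAssignment | None = None
    for k in range(k_min, k_max + 1):
        a = cut_tree(t, k)
        a.mean_silhouette = mean_silhouette(d, a)
        if best is None or a.mean_silhouette > best.mean_silhouette:
            best = a
    assert best is not None
    return best
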