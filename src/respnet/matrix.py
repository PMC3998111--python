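"""Binary interaction matrix and similarity-space hierarchical clustering.

The network's adjacency is flattened to a symmetric 0/1 matrix (diagonal 1
iff a self-interaction); rows are compared by uncentered correlation (cosine
on raw values, no mean-centering) and agglomerated with average linkage,
where cluster-cluster similarity is the unweighted mean of all cross-pair
similarities.  Clusters are extracted by cutting the merge tree at a
similarity threshold and keeping subtrees of at least two leaves; inflection
points of the clustered-node-count curve locate natural thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import InteractionNetwork, NetworkError

__all__ = [
    "BinaryMatrix",
    "MergeTree",
    "DendrogramCut",
    "build_binary_matrix",
    "uncentered_correlation",
    "similarity_matrix",
    "average_linkage",
    "cut_at_similarity",
    "clustered_node_curve",
    "detect_inflections",
    "export_cdt_gtr",
]


@dataclass
class BinaryMatrix:
    """Symmetric 0/1 interaction matrix with its node order."""

    ids: list
    values: np.ndarray  # (n, n) int8, symmetric

    @property
    def n(self) -> int:
        return len(self.ids)


def build_binary_matrix(
    net: InteractionNetwork, include_isolated: bool = False
) -> BinaryMatrix:
    """Adjacency of the network as a binary matrix in lexicographic node
    order.  Nodes without any interaction have an all-zero row (undefined
    similarity) and are excluded unless ``include_isolated`` is set."""
    if net.number_of_nodes() == 0:
        raise NetworkError("cannot build a matrix from an empty network")
    ids = net.nodes()
    index = {v: i for i, v in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=np.int8)
    for a, b, _ in net.edges():
        m[index[a], index[b]] = m[index[b], index[a]] = 1
    if not include_isolated:
        keep = m.any(axis=1)
        ids = [v for v, k in zip(ids, keep) if k]
        m = m[np.ix_(keep, keep)]
        if not ids:
            raise NetworkError("network has no interactions")
    return BinaryMatrix(ids, m)


def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sum(x*y) / (sqrt(sum x^2) * sqrt(sum y^2)); 0 if either vector is
    all-zero.  On binary vectors this equals cosine similarity."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise NetworkError("vectors must be one-dimensional with equal length >= 1")
    nx_ = math.sqrt(float(x @ x))
    ny_ = math.sqrt(float(y @ y))
    if nx_ == 0.0 or ny_ == 0.0:
        return 0.0
    return float(x @ y) / (nx_ * ny_)


def similarity_matrix(matrix: BinaryMatrix) -> np.ndarray:
    """All-pairs uncentered correlation between rows."""
    x = matrix.values.astype(float)
    norms = np.sqrt((x * x).sum(axis=1))
    safe = np.where(norms == 0.0, 1.0, norms)
    s = (x @ x.T) / np.outer(safe, safe)
    s[norms == 0.0, :] = 0.0
    s[:, norms == 0.0] = 0.0
    return s


@dataclass
class MergeTree:
    """Agglomeration record.

    ``merges`` is a list of ``(left, right, similarity, size)`` where leaves
    are numbered ``0..n-1`` and the cluster formed by merge ``i`` is
    ``n + i``.  Merge similarities are non-increasing (average linkage has no
    inversions).
    """

    ids: list
    merges: list

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def leaves_of(self, cluster: int) -> list[int]:
        n = self.n_leaves
        stack, out = [cluster], []
        while stack:
            c = stack.pop()
            if c < n:
                out.append(c)
            else:
                left, right, _, _ = self.merges[c - n]
                stack.extend((left, right))
        return sorted(out)


def average_linkage(matrix: BinaryMatrix) -> MergeTree:
    """Agglomerative clustering of matrix rows by uncentered correlation.

    Cluster-cluster similarity is the unweighted mean of cross-pair
    similarities; the most similar pair merges first.  Equal-similarity ties
    break lexicographically on the smallest member node id of each cluster.
    """
    n = matrix.n
    if n < 2:
        raise NetworkError("need at least 2 rows to cluster")
    # pairwise-similarity *sums* between clusters: cross-pair sums are
    # additive under merging, so the mean is exact on division
    s_sum = similarity_matrix(matrix).astype(float)
    sizes = np.ones(n, dtype=float)
    cluster_id = np.arange(n)  # cluster id occupying each row slot
    min_label = [str(v) for v in matrix.ids]
    alive = np.ones(n, dtype=bool)
    merges: list = []
    for step in range(n - 1):
        rows = np.nonzero(alive)[0]
        sim = s_sum[np.ix_(rows, rows)] / np.outer(sizes[rows], sizes[rows])
        iu = np.triu_indices(len(rows), k=1)
        vals = sim[iu]
        best = vals.max()
        tied = np.nonzero(vals >= best - 1e-15)[0]
        # tie-break: lexicographically smallest (min-member, min-member) pair
        def _key(t: int) -> tuple:
            ra, rb = rows[iu[0][t]], rows[iu[1][t]]
            return tuple(sorted((min_label[ra], min_label[rb])))
        t = min(tied, key=_key)
        ra, rb = rows[iu[0][t]], rows[iu[1][t]]
        sim_ab = s_sum[ra, rb] / (sizes[ra] * sizes[rb])
        merges.append(
            (int(cluster_id[ra]), int(cluster_id[rb]), float(sim_ab), int(sizes[ra] + sizes[rb]))
        )
        s_sum[ra, :] += s_sum[rb, :]
        s_sum[:, ra] = s_sum[ra, :]
        sizes[ra] += sizes[rb]
        min_label[ra] = min(min_label[ra], min_label[rb])
        cluster_id[ra] = n + step
        alive[rb] = False
    return MergeTree(list(matrix.ids), merges)


@dataclass
class DendrogramCut:
    """Clusters of >= 2 nodes obtained at a similarity threshold."""

    threshold: float
    clusters: list  # list of sorted node-id lists

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def min_size(self) -> int:
        return min((len(c) for c in self.clusters), default=0)

    @property
    def max_size(self) -> int:
        return max((len(c) for c in self.clusters), default=0)


def cut_at_similarity(tree: MergeTree, threshold: float) -> DendrogramCut:
    """Maximal subtrees whose internal merges all reach the threshold.

    Because average-linkage merge similarities are non-increasing, these are
    the connected groups formed by applying every merge with similarity >=
    threshold.  Only clusters with at least 2 leaves are reported.
    """
    if not 0.0 <= threshold <= 1.0:
        raise NetworkError(f"threshold {threshold} outside [0, 1]")
    n = tree.n_leaves
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (left, right, sim, _) in enumerate(tree.merges):
        if sim >= threshold:
            c = n + i
            parent[find(left)] = c
            parent[find(right)] = c
    groups: dict[int, list] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(tree.ids[leaf])
    clusters = sorted(
        (sorted(g) for g in groups.values() if len(g) >= 2), key=lambda c: c[0]
    )
    return DendrogramCut(threshold, clusters)


def clustered_node_curve(
    tree: MergeTree, thresholds: Sequence[float]
) -> list[tuple[float, int]]:
    """Total leaves inside >= 2-node clusters at each threshold (a
    non-increasing curve)."""
    thresholds = list(thresholds)
    if not thresholds:
        raise NetworkError("threshold grid must be non-empty")
    out = []
    for t in thresholds:
        cut = cut_at_similarity(tree, t)
        out.append((float(t), sum(len(c) for c in cut.clusters)))
    return out


def detect_inflections(curve: Sequence[tuple[float, int]]) -> list[float]:
    """Thresholds where the curve's discrete second difference changes sign
    after 3-point moving-average smoothing.

    Each maximal run of same-sign curvature contributes one threshold: the
    point of largest curvature magnitude (middle of the run under ties, which
    centers the symmetric smoothing of a sharp knee).  A linear curve has no
    inflections.  Requires at least 5 curve points.
    """
    curve = list(curve)
    if len(curve) < 5:
        raise NetworkError("inflection detection needs at least 5 curve points")
    t = np.array([p[0] for p in curve], dtype=float)
    y = np.array([p[1] for p in curve], dtype=float)
    smooth = y.copy()
    smooth[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    d2 = smooth[2:] - 2.0 * smooth[1:-1] + smooth[:-2]  # at indices 1..m-2
    sign = np.sign(np.where(np.abs(d2) < 1e-9, 0.0, d2))
    out: list[float] = []
    i = 0
    while i < len(sign):
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(sign) and sign[j + 1] == sign[i]:
            j += 1
        run = np.arange(i, j + 1)
        mags = np.abs(d2[run])
        tied = run[np.isclose(mags, mags.max())]
        pick = tied[len(tied) // 2]
        out.append(float(t[pick + 1]))
        i = j + 1
    return out


def export_cdt_gtr(
    matrix: BinaryMatrix, tree: MergeTree, base_path: str | Path
) -> tuple[Path, Path]:
    """Clustered-data-table (.cdt) and gene-tree (.gtr) text exports in the
    dendrogram-viewer dialect; leaf order follows the tree traversal."""
    base = Path(base_path)
    cdt_p = base.with_suffix(".cdt")
    gtr_p = base.with_suffix(".gtr")
    n = tree.n_leaves

    order: list[int] = []

    def _walk(c: int) -> None:
        if c < n:
            order.append(c)
        else:
            left, right, _, _ = tree.merges[c - n]
            _walk(left)
            _walk(right)

    roots = set(range(n + len(tree.merges)))
    for left, right, _, _ in tree.merges:
        roots.discard(left)
        roots.discard(right)
    for r in sorted(roots):
        _walk(r)

    def _name(c: int) -> str:
        return f"GENE{c}X" if c < n else f"NODE{c - n + 1}X"

    with gtr_p.open("w", encoding="utf-8") as fh:
        for i, (left, right, sim, _) in enumerate(tree.merges):
            fh.write(f"NODE{i + 1}X\t{_name(left)}\t{_name(right)}\t{sim:.6f}\n")
    with cdt_p.open("w", encoding="utf-8") as fh:
        cols = "\t".join(str(v) for v in matrix.ids)
        fh.write(f"GID\tNAME\tGWEIGHT\t{cols}\n")
        for leaf in order:
            row = "\t".join(str(int(v)) for v in matrix.values[leaf])
            fh.write(f"GENE{leaf}X\t{matrix.ids[leaf]}\t1\t{row}\n")
    return cdt_p, gtr_p
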