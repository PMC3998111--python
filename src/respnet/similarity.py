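"""Jaccard neighbor-set similarity and its statistical comparisons.

The Jaccard coefficient of two nodes is the intersection of their neighbor
sets divided by the union, where a neighbor set contains the node itself iff
it has a self-interaction.  Linked pairs are compared with unlinked pairs per
pair class (disease-gene, disease-chemical, chemical-gene) with a one-sided
Mann-Whitney U test; within sub-networks, pair similarities are ranked into
percentile bands (upper/middle/lower quartile split).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import InteractionNetwork, NetworkError, pair_class

__all__ = [
    "ComparisonResult",
    "neighbor_set",
    "jaccard",
    "jaccard_matrix",
    "jaccard_table",
    "compare_linked_unlinked",
    "subnetwork_percentile",
    "node_mean_similarity",
    "midrank_percentile",
]

COMPARISON_CLASSES = ("DG", "DC", "CG")


def neighbor_set(net: InteractionNetwork, node: str) -> set[str]:
    """All interaction partners of ``node``, including itself iff it has a
    self-interaction."""
    return net.neighbor_set(node)


def jaccard(net: InteractionNetwork, a: str, b: str) -> float:
    """|N(a) ∩ N(b)| / |N(a) ∪ N(b)|; defined as 0 when both sets are empty."""
    na, nb = net.neighbor_set(a), net.neighbor_set(b)
    inter = len(na & nb)
    union = len(na) + len(nb) - inter
    return inter / union if union else 0.0


def jaccard_matrix(net: InteractionNetwork) -> tuple[list[str], np.ndarray]:
    """All-pairs Jaccard coefficients as a dense symmetric matrix.

    Returns the sorted node-id order and the matrix (diagonal is the
    self-similarity, 1 unless the neighbor set is empty).
    """
    ids = net.nodes()
    n = len(ids)
    index = {v: i for i, v in enumerate(ids)}
    A = np.zeros((n, n), dtype=np.int32)
    for a, b, _ in net.edges():
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = 1  # a self-loop sets the diagonal
    inter = A @ A
    sizes = A.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return ids, J


@dataclass
class ComparisonResult:
    """Linked-vs-unlinked similarity comparison for one pair class."""

    pair_class: str
    n_linked: int
    n_unlinked: int
    median_linked: float
    median_unlinked: float
    u_statistic: float
    p_value: float


def _class_pair_indices(net: InteractionNetwork, ids: list[str], cls: str) -> np.ndarray:
    kinds = np.array([net.kind(v) for v in ids])
    groups = {
        "DG": ("disease", "gene"),
        "DC": ("disease", "chemical"),
        "CG": ("chemical", "gene"),
        "GG": ("gene", "gene"),
        "CC": ("chemical", "chemical"),
        "DD": ("disease", "disease"),
    }
    ka, kb = groups[cls]
    ia = np.nonzero(kinds == ka)[0]
    ib = np.nonzero(kinds == kb)[0]
    if ka == kb:
        pairs = [(i, j) for x, i in enumerate(ia) for j in ia[x + 1 :]]
    else:
        pairs = [(i, j) for i in ia for j in ib]
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def jaccard_table(
    net: InteractionNetwork, classes: tuple[str, ...] = COMPARISON_CLASSES
) -> pd.DataFrame:
    """All within-class pairs with coefficient, linked flag and class label."""
    ids, J = jaccard_matrix(net)
    adj = np.zeros_like(J, dtype=bool)
    index = {v: i for i, v in enumerate(ids)}
    for a, b, _ in net.edges():
        adj[index[a], index[b]] = adj[index[b], index[a]] = True
    frames = []
    for cls in classes:
        pairs = _class_pair_indices(net, ids, cls)
        if len(pairs) == 0:
            frames.append(
                pd.DataFrame(columns=["node_a", "node_b", "pair_class", "linked", "coefficient"])
            )
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        frames.append(
            pd.DataFrame(
                {
                    "node_a": np.array(ids, dtype=object)[np.minimum(i, j)],
                    "node_b": np.array(ids, dtype=object)[np.maximum(i, j)],
                    "pair_class": cls,
                    "linked": adj[i, j],
                    "coefficient": J[i, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compare_linked_unlinked(
    net: InteractionNetwork, classes: tuple[str, ...] = COMPARISON_CLASSES
) -> list[ComparisonResult]:
    """One-sided Mann-Whitney U test per pair class.

    Alternative hypothesis: linked pairs are stochastically more similar than
    unlinked pairs.  Uses the tie-corrected normal approximation.  A class
    without at least one linked and one unlinked pair raises an error naming
    the class.
    """
    table = jaccard_table(net, classes)
    results = []
    for cls in classes:
        if table.empty:
            raise NetworkError(
                f"pair class {cls} is degenerate (0 linked / 0 unlinked pairs)"
            )
        sub = table[table["pair_class"] == cls]
        linked = sub[sub["linked"]]["coefficient"].to_numpy()
        unlinked = sub[~sub["linked"]]["coefficient"].to_numpy()
        if len(linked) == 0 or len(unlinked) == 0:
            raise NetworkError(
                f"pair class {cls} is degenerate "
                f"({len(linked)} linked / {len(unlinked)} unlinked pairs)"
            )
        u, p = stats.mannwhitneyu(linked, unlinked, alternative="greater", method="asymptotic")
        results.append(
            ComparisonResult(
                pair_class=cls,
                n_linked=len(linked),
                n_unlinked=len(unlinked),
                median_linked=float(np.median(linked)),
                median_unlinked=float(np.median(unlinked)),
                u_statistic=float(u),
                p_value=float(p),
            )
        )
    return results


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def midrank_percentile(value: float, reference: np.ndarray) -> float:
    """Mid-rank percentile of ``value`` within ``reference``: the fraction of
    reference values strictly below plus half the ties, times 100."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise NetworkError("empty reference distribution")
    below = np.count_nonzero(reference < value)
    ties = np.count_nonzero(reference == value)
    return 100.0 * (below + 0.5 * ties) / reference.size


def _all_pair_coefficients(subnet: InteractionNetwork) -> tuple[list[tuple[str, str]], np.ndarray]:
    ids, J = jaccard_matrix(subnet)
    iu = np.triu_indices(len(ids), k=1)
    pairs = [(ids[i], ids[j]) for i, j in zip(*iu)]
    return pairs, J[iu]


def subnetwork_percentile(
    subnet: InteractionNetwork, pair: tuple[str, str]
) -> tuple[float, str]:
    """Percentile rank of a pair's Jaccard coefficient among all other
    unordered pairs of the sub-network, with its quartile band.

    The reference distribution excludes the query pair itself (a unique
    maximum therefore ranks at 100; an all-tied sub-network ranks every pair
    at 50, the middle band).  Bands: ``upper25`` for percentile >= 75,
    ``lower25`` for <= 25, ``middle`` otherwise.
    """
    a, b = pair
    if a not in subnet.graph or b not in subnet.graph:
        raise NetworkError(f"pair ({a!r}, {b!r}) is not inside the sub-network")
    if subnet.number_of_nodes() < 3:
        raise NetworkError("sub-network must have at least 3 nodes")
    pairs, coeffs = _all_pair_coefficients(subnet)
    key = tuple(sorted((a, b)))
    mask = np.array([p != key for p in pairs])
    value = jaccard(subnet, a, b)
    pct = midrank_percentile(value, coeffs[mask])
    if pct >= 75.0:
        band = "upper25"
    elif pct <= 25.0:
        band = "lower25"
    else:
        band = "middle"
    return pct, band


def node_mean_similarity(subnet: InteractionNetwork) -> dict[str, float]:
    """Mean Jaccard coefficient of each node to every other sub-network node
    (how similar a node is to the sub-network as a whole)."""
    if subnet.number_of_nodes() < 2:
        raise NetworkError("sub-network must have at least 2 nodes")
    ids, J = jaccard_matrix(subnet)
    n = len(ids)
    off = J.sum(axis=1) - np.diag(J)
    return {v: float(off[i] / (n - 1)) for i, v in enumerate(ids)}


def export_jaccard_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
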