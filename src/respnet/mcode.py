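"""Molecular-complex detection (MCODE-style vertex weighting and expansion).

Vertices are weighted by the density of the highest k-core of their closed
neighborhood scaled by that core's order; complexes grow greedily from
high-weight seeds, admitting neighbors whose weight is within a percentage
cutoff of the seed's.  Typed edges are treated as unweighted simple edges
(self-loops ignored); the mixed gene-chemical-disease network is clustered as
one graph.

Determinism choices where the classical algorithm is order-dependent: ties in
vertex weight break lexicographically by node id, zero-weight nodes never
seed, expansion consumes every reached node (so complexes are disjoint even
when post-processing trims members), and the haircut iteratively removes
degree-1 members (reducing a complex to its 2-core).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import InteractionNetwork, NetworkError

__all__ = ["McodeParams", "Complex", "vertex_weights", "find_complexes", "complexes_frame"]


@dataclass(frozen=True)
class McodeParams:
    """Published default parameters: degree cutoff 2, node score cutoff 0.2,
    k-core 2, max depth 100; haircut on, fluff off."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def validate(self) -> "McodeParams":
        if self.degree_cutoff < 0:
            raise NetworkError("degree_cutoff must be >= 0")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise NetworkError("node_score_cutoff must be in [0, 1]")
        if self.k_core < 0 or self.max_depth < 0:
            raise NetworkError("k_core and max_depth must be >= 0")
        return self


@dataclass
class Complex:
    """One detected complex: members, the seed it grew from, and its score
    (subgraph density times size)."""

    members: frozenset
    seed: str
    score: float

    def __len__(self) -> int:
        return len(self.members)


def _as_simple_graph(net: InteractionNetwork | nx.Graph) -> nx.Graph:
    if isinstance(net, InteractionNetwork):
        return net.simple_graph()
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for a, b in net.edges if a != b)
    return g


def vertex_weights(
    net: InteractionNetwork | nx.Graph, params: McodeParams | None = None
) -> dict[str, float]:
    """Core-weighted clustering density of every vertex.

    A vertex with degree below the degree cutoff weighs 0.  Otherwise its
    weight is ``k * density`` of the highest k-core of the subgraph induced
    by its closed neighborhood, where ``k`` is that core's order.
    """
    params = (params or McodeParams()).validate()
    g = _as_simple_graph(net)
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(g[v]) | {v}
        h = g.subgraph(closed)
        core_numbers = nx.core_number(h)
        kmax = max(core_numbers.values())
        if kmax == 0:
            weights[v] = 0.0
            continue
        core = h.subgraph([u for u, c in core_numbers.items() if c >= kmax])
        weights[v] = kmax * nx.density(core)
    return weights


def _two_core(g: nx.Graph, members: set, k: int = 2) -> set:
    """Iteratively strip members with internal degree below ``k``."""
    sub = g.subgraph(members).copy()
    while True:
        low = [v for v in sub.nodes if sub.degree(v) < k]
        if not low:
            return set(sub.nodes)
        sub.remove_nodes_from(low)


def find_complexes(
    net: InteractionNetwork | nx.Graph, params: McodeParams | None = None
) -> list[Complex]:
    """Greedy seeded complex prediction.

    Seeds are taken in descending weight order (ties by node id); expansion
    is a breadth-first search admitting unassigned neighbors with weight at
    least ``seed_weight * (1 - node_score_cutoff)``, up to ``max_depth`` from
    the seed.  Post-processing applies the haircut (2-core trim), optional
    fluff, drops complexes lacking a ``k_core``-core or their seed, and sorts
    the survivors by score descending.
    """
    params = (params or McodeParams()).validate()
    g = _as_simple_graph(net)
    if g.number_of_nodes() == 0:
        return []
    weights = vertex_weights(g, params)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        queue = deque([(seed, 0)])
        while queue:
            v, depth = queue.popleft()
            if depth >= params.max_depth:
                continue
            for u in sorted(g[v]):
                if u in members or u in assigned or weights[u] < threshold:
                    continue
                members.add(u)
                queue.append((u, depth + 1))
        assigned |= members  # consumed even if trimmed below
        kept = set(members)
        if params.haircut:
            kept = _two_core(g, kept, 2)
        if params.fluff:
            extra = set()
            for v in sorted(kept):
                for u in sorted(g[v]):
                    if u in kept or u in assigned or u in extra:
                        continue
                    closed = set(g[u]) | {u}
                    if nx.density(g.subgraph(closed)) >= params.node_score_cutoff:
                        extra.add(u)
            kept |= extra
            assigned |= extra
        if seed not in kept:
            continue
        # restrict to the seed's connected component (trims can disconnect)
        comp = nx.node_connected_component(g.subgraph(kept), seed)
        kept = set(comp)
        if len(kept) < 2:
            continue
        if params.k_core > 0 and not _two_core(g, kept, params.k_core):
            continue
        sub = g.subgraph(kept)
        score = nx.density(sub) * len(kept)
        complexes.append(Complex(frozenset(kept), seed, float(score)))
    complexes.sort(key=lambda c: (-c.score, c.seed))
    return complexes


def complexes_frame(complexes: list[Complex]) -> pd.DataFrame:
    """Tabular export: one row per complex with sorted member list."""
    return pd.DataFrame(
        {
            "complex": np.arange(1, len(complexes) + 1) if complexes else [],
            "score": [c.score for c in complexes],
            "size": [len(c) for c in complexes],
            "seed": [c.seed for c in complexes],
            "members": [";".join(sorted(c.members)) for c in complexes],
        }
    )
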