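"""Typed tripartite interaction networks.

The data model used throughout the package: an undirected network over three
node classes (gene, chemical, disease) whose edges carry an interaction
annotation (curation types such as ``therapeutic`` or ``increases`` plus
optional protein-modification tags).  Five edge classes are admissible --
gene-gene, gene-chemical, chemical-chemical, disease-gene, disease-chemical;
disease-disease links do not exist in the model.  All links are undirected and
self-interactions are permitted for genes only (protein self-interactions).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "NODE_KINDS",
    "RAW_TYPES",
    "MODIFICATIONS",
    "EDGE_CLASSES",
    "NetworkError",
    "ParseError",
    "EdgeAnnotation",
    "TripleRecord",
    "InteractionNetwork",
    "NetworkSummary",
    "pair_class",
    "edge_class",
    "summarize",
    "load_triples",
    "save_triples",
    "export_sif",
    "load_sif",
]

NODE_KINDS = ("gene", "chemical", "disease")

POSITIVE_TYPES = frozenset({"therapeutic", "increases"})
NEGATIVE_TYPES = frozenset({"marker/mechanism", "decreases"})
RAW_TYPES = POSITIVE_TYPES | NEGATIVE_TYPES | frozenset({"affects"})

MODIFICATIONS = frozenset(
    {
        "ubiquitination",
        "phosphorylation",
        "oxidation",
        "cleavage",
        "methylation",
        "hydrolysis",
        "hydroxylation",
        "glycosylation",
        "glucuronidation",
        "acetylation",
        "nitrosation",
        "ribosylation",
    }
)

#: two-letter pair-class code keyed by the (sorted) pair of node kinds
_PAIR_CODE = {
    ("gene", "gene"): "GG",
    ("chemical", "gene"): "CG",
    ("chemical", "chemical"): "CC",
    ("disease", "gene"): "DG",
    ("chemical", "disease"): "DC",
    ("disease", "disease"): "DD",
}

EDGE_CLASSES = (
    "gene-gene",
    "gene-chemical",
    "chemical-chemical",
    "disease-gene",
    "disease-chemical",
)

_EDGE_CLASS_BY_CODE = {
    "GG": "gene-gene",
    "CG": "gene-chemical",
    "CC": "chemical-chemical",
    "DG": "disease-gene",
    "DC": "disease-chemical",
}


class NetworkError(ValueError):
    """Raised for violations of the network data-model invariants."""


class ParseError(NetworkError):
    """Raised for malformed rows in network files; names the line number."""


def pair_class(kind_a: str, kind_b: str) -> str:
    """Two-letter class code for a pair of node kinds (``DG``, ``CG``, ...).

    ``DD`` is a valid *pair* class (used when classifying similarity
    coefficients between disease pairs) but never a valid *edge* class.
    """
    try:
        return _PAIR_CODE[tuple(sorted((kind_a, kind_b)))]
    except KeyError:
        raise NetworkError(f"unknown node kinds: {kind_a!r}, {kind_b!r}") from None


def edge_class(kind_a: str, kind_b: str) -> str:
    """Edge-class label for two node kinds; disease-disease is rejected."""
    code = pair_class(kind_a, kind_b)
    if code == "DD":
        raise NetworkError("disease-disease links are not permitted")
    return _EDGE_CLASS_BY_CODE[code]


@dataclass(frozen=True)
class EdgeAnnotation:
    """Interaction annotation carried by one undirected edge.

    ``raw_types`` is a subset of the closed curation vocabulary; ``polarity``
    is derived: positive iff the types are all positive-leaning (therapeutic /
    increases), negative iff all negative-leaning (marker-mechanism /
    decreases), mixed otherwise -- including ``affects``, conflicting type
    sets, and the empty set (untyped edges such as protein-protein links).
    """

    raw_types: frozenset = frozenset()
    modifications: frozenset = frozenset()

    def __post_init__(self) -> None:
        raw = frozenset(self.raw_types)
        mods = frozenset(self.modifications)
        object.__setattr__(self, "raw_types", raw)
        object.__setattr__(self, "modifications", mods)
        bad = raw - RAW_TYPES
        if bad:
            raise NetworkError(f"unknown interaction types: {sorted(bad)}")
        bad = mods - MODIFICATIONS
        if bad:
            raise NetworkError(f"unknown protein modifications: {sorted(bad)}")

    @property
    def polarity(self) -> str:
        if self.raw_types and self.raw_types <= POSITIVE_TYPES:
            return "positive"
        if self.raw_types and self.raw_types <= NEGATIVE_TYPES:
            return "negative"
        return "mixed"

    def merge(self, other: "EdgeAnnotation") -> "EdgeAnnotation":
        """Union of two annotations (duplicate-row collapse rule)."""
        return EdgeAnnotation(
            self.raw_types | other.raw_types,
            self.modifications | other.modifications,
        )


@dataclass(frozen=True)
class TripleRecord:
    """One (node, node, annotation) interaction triple."""

    a: str
    b: str
    annotation: EdgeAnnotation = field(default_factory=EdgeAnnotation)


class InteractionNetwork:
    """Undirected typed tripartite network.

    Thin wrapper over a :class:`networkx.Graph` that enforces the model
    invariants: node ids are non-empty, unique across kinds, edges connect
    existing nodes, disease-disease edges are rejected, and self-loops are
    gene-gene only.  Edge annotations merge (type union) when the same
    unordered pair is added twice.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, kind: str) -> str:
        node_id = str(node_id).strip()
        if not node_id:
            raise NetworkError("node id must be non-empty")
        if kind not in NODE_KINDS:
            raise NetworkError(f"unknown node kind {kind!r} for node {node_id!r}")
        existing = self._g.nodes.get(node_id)
        if existing is not None and existing["kind"] != kind:
            raise NetworkError(
                f"node {node_id!r} declared both {existing['kind']!r} and {kind!r}"
            )
        self._g.add_node(node_id, kind=kind)
        return node_id

    def add_edge(
        self,
        a: str,
        b: str,
        annotation: EdgeAnnotation | None = None,
        kind_a: str | None = None,
        kind_b: str | None = None,
    ) -> None:
        if kind_a is not None:
            a = self.add_node(a, kind_a)
        else:
            a = str(a).strip()
        if kind_b is not None:
            b = self.add_node(b, kind_b)
        else:
            b = str(b).strip()
        for n in (a, b):
            if n not in self._g:
                raise NetworkError(f"edge endpoint {n!r} is not a declared node")
        cls = edge_class(self.kind(a), self.kind(b))  # rejects disease-disease
        if a == b and cls != "gene-gene":
            raise NetworkError(f"self-interaction on non-gene node {a!r}")
        annotation = annotation or EdgeAnnotation()
        if self._g.has_edge(a, b):
            annotation = self._g.edges[a, b]["annotation"].merge(annotation)
        self._g.add_edge(a, b, annotation=annotation)

    # -- access -----------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    def kind(self, node_id: str) -> str:
        try:
            return self._g.nodes[node_id]["kind"]
        except KeyError:
            raise NetworkError(f"unknown node {node_id!r}") from None

    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self._g.nodes(data=True) if d["kind"] == kind)

    def edges(self) -> Iterator[tuple[str, str, EdgeAnnotation]]:
        for a, b, d in self._g.edges(data=True):
            x, y = sorted((a, b))
            yield x, y, d["annotation"]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def annotation(self, a: str, b: str) -> EdgeAnnotation:
        try:
            return self._g.edges[a, b]["annotation"]
        except KeyError:
            raise NetworkError(f"no edge between {a!r} and {b!r}") from None

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbor_set(self, node_id: str) -> set[str]:
        """Interaction partners of a node; contains the node itself iff it
        has a self-interaction (the neighbor-set convention used by the
        Jaccard similarity)."""
        if node_id not in self._g:
            raise NetworkError(f"unknown node {node_id!r}")
        return set(self._g[node_id])

    def subnetwork(self, nodes: Iterable[str]) -> "InteractionNetwork":
        """Induced sub-network on ``nodes`` (nodes, kinds and internal edges)."""
        nodes = list(nodes)
        for n in nodes:
            self.kind(n)  # raises on unknowns
        sub = InteractionNetwork()
        sub._g = self._g.subgraph(nodes).copy()
        return sub

    def simple_graph(self) -> nx.Graph:
        """Untyped simple-graph view: self-loops removed, annotations dropped."""
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        g.add_edges_from((a, b) for a, b in self._g.edges if a != b)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        if dict(self._g.nodes(data="kind")) != dict(other._g.nodes(data="kind")):
            return False
        mine = {frozenset((a, b)) or frozenset((a,)): ann for a, b, ann in self.edges()}
        theirs = {
            frozenset((a, b)) or frozenset((a,)): ann for a, b, ann in other.edges()
        }
        return mine == theirs

    def __repr__(self) -> str:
        return (
            f"<InteractionNetwork nodes={self.number_of_nodes()} "
            f"edges={self.number_of_edges()}>"
        )


@dataclass
class NetworkSummary:
    """Printed summary statistics of a network."""

    node_counts: Mapping[str, int]
    link_counts: Mapping[str, int]
    total_nodes: int
    total_links: int
    mean_neighbors: float
    link_probability: float
    characteristic_path_length: float

    def as_dict(self) -> dict:
        d = {f"nodes_{k}": v for k, v in self.node_counts.items()}
        d.update({f"links_{k}": v for k, v in self.link_counts.items()})
        d.update(
            total_nodes=self.total_nodes,
            total_links=self.total_links,
            mean_neighbors=self.mean_neighbors,
            link_probability=self.link_probability,
            characteristic_path_length=self.characteristic_path_length,
        )
        return d


def mean_neighbors_from_counts(total_nodes: int, total_links: int) -> float:
    """Average neighbor count implied by node/link totals (2L/N)."""
    if total_nodes == 0:
        return math.nan
    return 2.0 * total_links / total_nodes


def link_probability_from_counts(total_nodes: int, total_links: int) -> float:
    """Probability that two randomly chosen nodes are linked: L / C(N, 2)."""
    n_pairs = total_nodes * (total_nodes - 1) / 2.0
    if n_pairs == 0:
        return math.nan
    return total_links / n_pairs


def summarize(net: InteractionNetwork) -> NetworkSummary:
    """Node/link counts, mean neighbors, link probability, and the
    characteristic (mean shortest) path length.

    Mean neighbors averages neighbor-set sizes, so a self-loop contributes
    once to its node's neighborhood.  The characteristic path length is the
    mean shortest-path length over connected unordered node pairs, computed on
    the largest connected component when the network is disconnected.  An
    empty network reports zero counts and NaN ratios.
    """
    g = net.graph
    node_counts = {k: 0 for k in NODE_KINDS}
    for _, kind in g.nodes(data="kind"):
        node_counts[kind] += 1
    link_counts = {c: 0 for c in EDGE_CLASSES}
    for a, b in g.edges:
        link_counts[edge_class(net.kind(a), net.kind(b))] += 1
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        return NetworkSummary(node_counts, link_counts, 0, 0, math.nan, math.nan, math.nan)
    mean_nb = sum(len(net.neighbor_set(v)) for v in g.nodes) / n
    link_p = link_probability_from_counts(n, m)
    simple = net.simple_graph()
    if simple.number_of_nodes() > 1:
        comp = max(nx.connected_components(simple), key=lambda c: (len(c), sorted(c)))
        if len(comp) > 1:
            cpl = nx.average_shortest_path_length(simple.subgraph(comp))
        else:
            cpl = math.nan
    else:
        cpl = math.nan
    return NetworkSummary(node_counts, link_counts, n, m, mean_nb, link_p, cpl)


# -- triple TSV dialect ---------------------------------------------------

_TRIPLE_COLUMNS = ("node_a", "node_b", "kind_a", "kind_b", "raw_types", "modifications")


def _join(items: frozenset) -> str:
    return ";".join(sorted(items))


def _split(text: str) -> frozenset:
    text = (text or "").strip()
    return frozenset(t.strip() for t in text.split(";") if t.strip())


def load_triples(path: str | Path) -> InteractionNetwork:
    """Read an edge-triple TSV (columns ``node_a, node_b, kind_a, kind_b,
    raw_types, modifications``; ``#`` lines are comments) into a network.

    Duplicate rows for the same unordered pair collapse to a single edge with
    merged interaction types.  Malformed rows, unknown node kinds, node-kind
    collisions and disease-disease rows raise :class:`ParseError` naming the
    line number.
    """
    path = Path(path)
    net = InteractionNetwork()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in _TRIPLE_COLUMNS[:4] if c not in header]
                if missing:
                    raise ParseError(
                        f"{path.name}:{lineno}: header lacks columns {missing}"
                    )
                idx = {c: header.index(c) for c in _TRIPLE_COLUMNS if c in header}
                continue
            try:
                a = row[idx["node_a"]].strip()
                b = row[idx["node_b"]].strip()
                ka = row[idx["kind_a"]].strip()
                kb = row[idx["kind_b"]].strip()
            except IndexError:
                raise ParseError(f"{path.name}:{lineno}: too few columns") from None
            raw = _split(row[idx["raw_types"]]) if "raw_types" in idx and len(row) > idx["raw_types"] else frozenset()
            mods = _split(row[idx["modifications"]]) if "modifications" in idx and len(row) > idx["modifications"] else frozenset()
            try:
                ann = EdgeAnnotation(raw, mods)
                net.add_edge(a, b, ann, kind_a=ka, kind_b=kb)
            except NetworkError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
        if header is None:
            raise ParseError(f"{path.name}: empty file without a header row")
    return net


def save_triples(
    net: InteractionNetwork, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a network in the edge-triple TSV dialect (sorted, canonical)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRIPLE_COLUMNS)
        for a, b, ann in sorted(net.edges()):
            w.writerow(
                [a, b, net.kind(a), net.kind(b), _join(ann.raw_types), _join(ann.modifications)]
            )


# -- SIF + attribute tables ----------------------------------------------


def export_sif(net: InteractionNetwork, base_path: str | Path) -> tuple[Path, Path, Path]:
    """Write ``<base>.sif`` (relation token = edge class) plus two attribute
    TSVs: ``<base>.node_attrs.tsv`` (node kind) and ``<base>.edge_attrs.tsv``
    (polarity, raw types, modifications).  Returns the three paths."""
    base = Path(base_path)
    sif = base.with_suffix(".sif")
    nodes_p = base.with_suffix(".node_attrs.tsv")
    edges_p = base.with_suffix(".edge_attrs.tsv")
    with sif.open("w", encoding="utf-8") as fh:
        for a, b, _ in sorted(net.edges()):
            fh.write(f"{a}\t{edge_class(net.kind(a), net.kind(b))}\t{b}\n")
        # isolated nodes: bare SIF lines keep them round-trippable
        linked = {n for a, b, _ in net.edges() for n in (a, b)}
        for n in net.nodes():
            if n not in linked:
                fh.write(f"{n}\n")
    with nodes_p.open("w", encoding="utf-8") as fh:
        fh.write("node\tkind\n")
        for n in net.nodes():
            fh.write(f"{n}\t{net.kind(n)}\n")
    with edges_p.open("w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tpolarity\traw_types\tmodifications\n")
        for a, b, ann in sorted(net.edges()):
            fh.write(
                f"{a}\t{b}\t{ann.polarity}\t{_join(ann.raw_types)}\t{_join(ann.modifications)}\n"
            )
    return sif, nodes_p, edges_p


def load_sif(base_path: str | Path) -> InteractionNetwork:
    """Re-import a network written by :func:`export_sif`."""
    base = Path(base_path)
    net = InteractionNetwork()
    with base.with_suffix(".node_attrs.tsv").open(encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            if line.strip():
                node, kind = line.rstrip("\n").split("\t")
                net.add_node(node, kind)
    with base.with_suffix(".edge_attrs.tsv").open(encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            a, b, _pol, raw, mods = (line.rstrip("\n").split("\t") + ["", ""])[:5]
            net.add_edge(a, b, EdgeAnnotation(_split(raw), _split(mods)))
    return net
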