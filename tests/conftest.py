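import pytest

from respnet import builder, synthetic
from respnet.core import EdgeAnnotation, InteractionNetwork


def make_network(nodes, edges):
    """Small-network builder: nodes = {id: kind}, edges = [(a, b)] or
    [(a, b, raw_types-iterable)]."""
    net = InteractionNetwork()
    for node_id, kind in nodes.items():
        net.add_node(node_id, kind)
    for edge in edges:
        a, b, *rest = edge
        ann = EdgeAnnotation(frozenset(rest[0])) if rest else EdgeAnnotation()
        net.add_edge(a, b, ann)
    return net


def gene_graph(edges, extra_nodes=()):
    """All-gene network from an edge list (for clustering/stability tests)."""
    nodes = {n: "gene" for e in edges for n in e}
    nodes.update({n: "gene" for n in extra_nodes})
    return make_network(nodes, edges)


def best_match_jaccard(block, node_sets):
    """Best node-set Jaccard overlap between a planted block and any of the
    recovered node sets."""
    block = set(block)
    return max(
        (len(block & set(s)) / len(block | set(s)) for s in node_sets), default=0.0
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic bundle (default configuration, seed 0)."""
    return synthetic.generate(synthetic.SynthesisConfig())


@pytest.fixture(scope="session")
def whole_net(default_bundle):
    return builder.build_whole_network(
        default_bundle.tables, set(default_bundle.diseases)
    )


@pytest.fixture(scope="session")
def therapeutic_net(default_bundle):
    return builder.build_therapeutic_network(
        default_bundle.tables, set(default_bundle.diseases)
    )
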