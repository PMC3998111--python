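"""Published reference counts for the respiratory interactome networks.

These are the printed node/link totals of the deposited whole-respiratory and
therapeutic gene-chemical-disease networks.  They serve as inputs for the
desk-arithmetic checks (link probability, mean neighbor count) and as the
expected values when the deposited edge tables themselves are available
locally (see ``data/published/`` in the repository layout).
"""

from __future__ import annotations

from .core import link_probability_from_counts, mean_neighbors_from_counts

__all__ = [
    "REFERENCE_NETWORK_COUNTS",
    "reference_link_probability",
    "reference_mean_neighbors",
]

REFERENCE_NETWORK_COUNTS: dict[str, dict] = {
    "whole": {
        "nodes": {"gene": 426, "chemical": 1177, "disease": 227},
        "links": {
            "gene-chemical": 13543,
            "gene-gene": 438,
            "chemical-chemical": 0,
            "disease-gene": 577,
            "disease-chemical": 2717,
        },
    },
    "therapeutic": {
        "nodes": {"gene": 388, "chemical": 578, "disease": 227},
        "links": {
            "gene-chemical": 7587,
            "gene-gene": 433,
            "chemical-chemical": 435,
            "disease-gene": 536,
            "disease-chemical": 1688,
        },
    },
}


def _totals(network: str) -> tuple[int, int]:
    entry = REFERENCE_NETWORK_COUNTS[network]
    return sum(entry["nodes"].values()), sum(entry["links"].values())


def reference_link_probability(network: str = "therapeutic") -> float:
    """Probability that two random nodes of the reference network are linked."""
    n, m = _totals(network)
    return link_probability_from_counts(n, m)


def reference_mean_neighbors(network: str = "therapeutic") -> float:
    """Mean neighbor count implied by the reference network's totals."""
    n, m = _totals(network)
    return mean_neighbors_from_counts(n, m)
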