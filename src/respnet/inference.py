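"""Candidate novel links and reference-network validation.

Two complementary procedures: (1) unlinked node pairs inside dense
sub-networks (complexes) are sampled as candidate novel interactions and
annotated with their within-sub-network Jaccard percentile band; (2) a
reference protein-protein network supplies gene pairs that are absent from
the study network -- their Jaccard coefficients are compared with the
background of all unlinked gene-gene pairs (one-sided Mann-Whitney U, plus a
decile histogram of percentile ranks) to test whether similarity predicts
interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import InteractionNetwork, NetworkError, pair_class
from .mcode import Complex
from .similarity import jaccard_matrix, subnetwork_percentile, jaccard

__all__ = [
    "CandidatePair",
    "CandidateSample",
    "ValidationResult",
    "candidates",
    "validate_against_reference",
]


@dataclass
class CandidatePair:
    """An unlinked within-complex pair proposed as a novel interaction."""

    node_a: str
    node_b: str
    subnet_id: int
    jaccard: float
    percentile: float
    band: str
    evidence: str = ""  # placeholder column for manual literature curation


@dataclass
class CandidateSample:
    pairs: list
    truncated: bool = False  # fewer unlinked pairs existed than requested

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])


def candidates(
    net: InteractionNetwork,
    complexes: list[Complex],
    n_sample: int,
    seed: int | None = None,
) -> CandidateSample:
    """Uniform seeded sample (without replacement) of unlinked within-complex
    pairs, each annotated with its sub-network Jaccard percentile band.

    Disease-disease pairs are excluded (the edge class does not exist).  If
    fewer unlinked pairs exist than requested, all are returned and the
    sample is flagged truncated.
    """
    if n_sample < 1:
        raise NetworkError("n_sample must be >= 1")
    pool: list[tuple[int, str, str]] = []
    for k, cx in enumerate(complexes):
        for a, b in combinations(sorted(cx.members), 2):
            if net.has_edge(a, b):
                continue
            if pair_class(net.kind(a), net.kind(b)) == "DD":
                continue
            pool.append((k, a, b))
    truncated = len(pool) < n_sample
    if truncated:
        warnings.warn(
            f"only {len(pool)} unlinked within-complex pairs available "
            f"({n_sample} requested)",
            stacklevel=2,
        )
        chosen = pool
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=n_sample, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    subnets = {k: net.subnetwork(sorted(cx.members)) for k, cx in enumerate(complexes)}
    out = []
    for k, a, b in chosen:
        sub = subnets[k]
        pct, band = subnetwork_percentile(sub, (a, b))
        out.append(CandidatePair(a, b, k, jaccard(sub, a, b), pct, band))
    return CandidateSample(out, truncated)


@dataclass
class ValidationResult:
    """Reference-network validation of similarity-based link prediction."""

    n_validation_pairs: int
    u_statistic: float
    u_p_value: float
    background_fraction: list  # 10 decile bins, sums to 1
    validation_fraction: list  # 10 decile bins, sums to 1

    def histogram_frame(self) -> pd.DataFrame:
        lo = np.arange(0, 100, 10)
        return pd.DataFrame(
            {
                "percentile_low": lo,
                "percentile_high": lo + 10,
                "background_fraction": self.background_fraction,
                "validation_fraction": self.validation_fraction,
            }
        )


def _decile_bins(values: np.ndarray, background_sorted: np.ndarray) -> np.ndarray:
    """Decile bin index (0..9) per value, with boundary ties assigned to the
    lower bin.

    Boundary values are the ordinal decile ranks of the background; a value
    equal to a boundary falls in the lower of the two bins it separates.
    """
    m = background_sorted.size
    ranks = [min(m - 1, int(np.ceil((i + 1) * m / 10.0)) - 1) for i in range(9)]
    boundaries = background_sorted[ranks]
    return np.searchsorted(boundaries, values, side="left").clip(0, 9)


def validate_against_reference(
    net: InteractionNetwork, reference_net: InteractionNetwork
) -> ValidationResult:
    """Test whether reference gene-gene interactions missing from the study
    network are more similar than the unlinked background.

    The validation set is every reference gene-gene edge whose two genes are
    present in the study network but whose edge is not, self-interactions
    excluded.  The background is every unlinked non-self gene-gene pair of
    the study network.  Self-interacting pairs contribute to neighbor sets
    but never to either sample (their similarity is trivially 1).
    """
    genes = set(net.nodes_of_kind("gene"))
    validation_pairs = []
    for a, b, _ in reference_net.edges():
        if a == b or a not in genes or b not in genes:
            continue
        if net.has_edge(a, b):
            continue
        validation_pairs.append(tuple(sorted((a, b))))
    validation_pairs = sorted(set(validation_pairs))
    if not validation_pairs:
        raise NetworkError("validation set is empty (no reference edge absent from the network)")

    ids, J = jaccard_matrix(net)
    index = {v: i for i, v in enumerate(ids)}
    gene_idx = np.array([index[g] for g in sorted(genes)])
    sub = J[np.ix_(gene_idx, gene_idx)]
    adj = np.zeros_like(sub, dtype=bool)
    gpos = {g: k for k, g in enumerate(sorted(genes))}
    for a, b, _ in net.edges():
        if a in gpos and b in gpos:
            adj[gpos[a], gpos[b]] = adj[gpos[b], gpos[a]] = True
    iu = np.triu_indices(len(gene_idx), k=1)
    unlinked = ~adj[iu]
    background = sub[iu][unlinked]

    val = np.array([J[index[a], index[b]] for a, b in validation_pairs])
    u, p = stats.mannwhitneyu(val, background, alternative="greater", method="asymptotic")

    bg_sorted = np.sort(background)
    bg_bins = _decile_bins(background, bg_sorted)
    val_bins = _decile_bins(val, bg_sorted)
    bg_frac = np.bincount(bg_bins, minlength=10) / background.size
    val_frac = np.bincount(val_bins, minlength=10) / val.size
    return ValidationResult(
        n_validation_pairs=len(validation_pairs),
        u_statistic=float(u),
        u_p_value=float(p),
        background_fraction=[float(f) for f in bg_frac],
        validation_fraction=[float(f) for f in val_frac],
    )
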