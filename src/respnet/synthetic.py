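"""Synthetic raw-table bundles with planted structure.

Emulates the statistical shape of the curated-database inputs so every
pipeline stage is testable without downloads: three node classes at the
published scale ratios, sparse per-class background densities (~1.5% of node
pairs linked), interaction-polarity labels from the closed vocabulary,
hub-dominated degree heterogeneity, planted dense mixed-kind clusters, a
co-occurrence mechanism embedding secondary chemicals in interaction text,
and a partially overlapping reference protein-protein network built from
withheld gene-gene edges (for link-inference validation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .builder import RawInteractionTables
from .core import EdgeAnnotation, InteractionNetwork, NetworkError, save_triples

__all__ = ["SynthesisConfig", "SyntheticBundle", "generate", "empirical_density"]

_BACKGROUND_CLASSES = ("gene-gene", "gene-chemical", "disease-gene", "disease-chemical")

#: fraction of chemical-gene rows emitted twice (the two query orientations)
_DUPLICATE_ROW_RATE = 0.25
#: per-gene probability of a protein self-interaction
_SELF_LOOP_RATE = 0.02
#: probability that a co-occurrence partner is drawn from the host's planted block
_BLOCK_PARTNER_RATE = 0.7


def _default_density() -> dict[str, float]:
    return {
        "gene-gene": 0.005,
        "gene-chemical": 0.015,
        "disease-gene": 0.015,
        "disease-chemical": 0.015,
    }


@dataclass(frozen=True)
class SynthesisConfig:
    """Generator settings.

    Defaults are fixed at roughly one quarter of the published network scale
    (100 genes, 150 chemicals, 60 diseases) with the published class ratios
    for the tunable fractions: about half the chemicals carry a therapeutic
    indication and about 6% of chemical-gene rows mention a second chemical.
    """

    n_genes: int = 100
    n_chemicals: int = 150
    n_diseases: int = 60
    density: Mapping[str, float] = field(default_factory=_default_density)
    n_planted_clusters: int = 3
    planted_cluster_size: int = 12
    planted_within_density: float = 0.9
    #: fraction of each planted block drawn from genes / chemicals / diseases
    planted_kind_mix: tuple = (0.75, 0.125, 0.125)
    therapeutic_fraction: float = 0.5
    cooccurrence_rate: float = 0.06
    reference_overlap: float = 0.15
    degree_heterogeneity: float = 0.4  # lognormal sigma, unit median
    seed: int = 0

    def validate(self) -> "SynthesisConfig":
        for name in ("n_genes", "n_chemicals", "n_diseases", "n_planted_clusters"):
            if getattr(self, name) < 0:
                raise NetworkError(f"{name} must be >= 0")
        probs = dict(self.density)
        probs.update(
            planted_within_density=self.planted_within_density,
            therapeutic_fraction=self.therapeutic_fraction,
            cooccurrence_rate=self.cooccurrence_rate,
            reference_overlap=self.reference_overlap,
        )
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise NetworkError(f"probability {name} = {p} outside [0, 1]")
        unknown = set(self.density) - set(_BACKGROUND_CLASSES)
        if unknown:
            raise NetworkError(f"unknown background density classes {sorted(unknown)}")
        if len(self.planted_kind_mix) != 3 or abs(sum(self.planted_kind_mix) - 1.0) > 1e-9:
            raise NetworkError("planted_kind_mix must be three fractions summing to 1")
        if self.n_planted_clusters:
            if self.planted_cluster_size < 3:
                raise NetworkError("planted_cluster_size must be >= 3")
            n_g, n_c, n_d = self.block_composition()
            if n_g * self.n_planted_clusters > self.n_genes:
                raise NetworkError("planted clusters need more genes than available")
            if n_c * self.n_planted_clusters > self.n_chemicals:
                raise NetworkError("planted clusters need more chemicals than available")
            if n_d * self.n_planted_clusters > self.n_diseases:
                raise NetworkError("planted clusters need more diseases than available")
        return self

    def block_composition(self) -> tuple[int, int, int]:
        """Genes / chemicals / diseases per planted block (genes absorb
        rounding so the three parts always sum to the block size)."""
        s = self.planted_cluster_size
        n_d = int(s * self.planted_kind_mix[2] + 0.5)
        n_c = int(s * self.planted_kind_mix[1] + 0.5)
        n_g = s - n_c - n_d
        if n_g < 1:
            raise NetworkError("planted_kind_mix leaves no genes in a block")
        return n_g, n_c, n_d


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground truth used to score recovery."""

    tables: RawInteractionTables
    truth: dict
    reference_net: InteractionNetwork
    diseases: list
    config: SynthesisConfig

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.tables.write_dir(directory)
        (directory / "diseases.txt").write_text(
            "\n".join(self.diseases) + "\n", encoding="utf-8"
        )
        save_triples(self.reference_net, directory / "reference_net.tsv")
        truth = {
            "clusters": [sorted(c) for c in self.truth["clusters"]],
            "withheld_edges": [list(e) for e in self.truth["withheld_edges"]],
        }
        (directory / "truth.yaml").write_text(
            yaml.safe_dump(truth, sort_keys=True), encoding="utf-8"
        )


def _names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _balanced_pairs(
    tagged_pairs: list, k: int, rng: np.random.Generator
) -> list:
    """Choose ``k`` of the given ``(tag, (a, b))`` pairs while spreading the
    per-node selection count as evenly as possible (greedy passes with an
    increasing per-node cap, shuffled order)."""
    if k <= 0:
        return []
    if k >= len(tagged_pairs):
        return list(tagged_pairs)
    order = [tagged_pairs[i] for i in rng.permutation(len(tagged_pairs))]
    counts: dict[str, int] = {}
    chosen: list = []
    chosen_keys: set = set()
    cap = 1
    while len(chosen) < k:
        for item in order:
            if len(chosen) >= k:
                break
            _, (a, b) = item
            key = id(item)
            if key in chosen_keys:
                continue
            if counts.get(a, 0) < cap and counts.get(b, 0) < cap:
                chosen.append(item)
                chosen_keys.add(key)
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
        cap += 1
    return chosen


def _sample_pairs(
    rng: np.random.Generator,
    a: list[str],
    b: list[str],
    base_p: float,
    prop_a: np.ndarray,
    prop_b: np.ndarray,
    same: bool,
) -> set[tuple[str, str]]:
    if not a or not b or base_p <= 0:
        return set()
    p = np.clip(base_p * np.outer(prop_a, prop_b), 0.0, 1.0)
    draw = rng.random(p.shape) < p
    if same:
        draw = np.triu(draw, k=1)
    ii, jj = np.nonzero(draw)
    if same:
        return {tuple(sorted((a[i], b[j]))) for i, j in zip(ii, jj)}
    return {(a[i], b[j]) for i, j in zip(ii, jj)}


_TYPE_CHOICES = (
    ("increases",),
    ("decreases",),
    ("affects",),
    ("increases", "decreases"),
)
_TYPE_WEIGHTS = (0.4, 0.35, 0.2, 0.05)
_VERB = {
    "increases": "results in increased expression of",
    "decreases": "results in decreased expression of",
    "affects": "affects the activity of",
}
_MODS = tuple(sorted(
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
))


def generate(config: SynthesisConfig) -> SyntheticBundle:
    """Draw a full synthetic bundle; identical seeds give identical output.

    Background edges are Bernoulli per admissible pair with a per-class base
    density modulated by per-node lognormal propensities (hub heterogeneity).
    Planted clusters are disjoint half-gene/half-chemical blocks whose
    admissible internal pairs (gene-gene and gene-chemical) link with
    probability ``planted_within_density``; each planted member is guaranteed
    at least one disease association so the disease-context filter keeps it.
    A ``reference_overlap`` fraction of planted gene-gene edges is withheld
    from the tables into the reference network, together with an equal number
    of random unlinked gene pairs as noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _names("G", config.n_genes)
    chems = _names("C", config.n_chemicals)
    diseases = _names("D", config.n_diseases)
    prop = {
        kind: np.exp(rng.normal(0.0, config.degree_heterogeneity, size=len(nodes)))
        for kind, nodes in (("gene", genes), ("chemical", chems), ("disease", diseases))
    }
    dens = {**_default_density(), **dict(config.density)}

    gg = _sample_pairs(rng, genes, genes, dens["gene-gene"], prop["gene"], prop["gene"], True)
    cg = _sample_pairs(rng, chems, genes, dens["gene-chemical"], prop["chemical"], prop["gene"], False)
    dg = _sample_pairs(rng, diseases, genes, dens["disease-gene"], prop["disease"], prop["gene"], False)
    dc = _sample_pairs(rng, diseases, chems, dens["disease-chemical"], prop["disease"], prop["chemical"], False)

    # planted dense mixed-kind blocks (disjoint): every admissible internal
    # pair class is densified (gene-gene, gene-chemical, disease-gene,
    # disease-chemical; chemical-chemical emerges later via co-occurrence).
    # Internal non-edges are placed degree-balanced, so every member carries
    # an equal share of the (1 - within_density) missing pairs: each block is
    # a near-regular planted cluster of the stated density rather than an
    # irregular Bernoulli draw.
    clusters: list[list[str]] = []
    planted_gg: set[tuple[str, str]] = set()
    block_of: dict[str, list[str]] = {}
    gene_pool = [str(v) for v in rng.permutation(genes)]
    chem_pool = [str(v) for v in rng.permutation(chems)]
    disease_pool = [str(v) for v in rng.permutation(diseases)]
    if config.n_planted_clusters:
        n_g_block, n_c_block, n_d_block = config.block_composition()
    for _ in range(config.n_planted_clusters):
        members_g = sorted(gene_pool.pop() for _ in range(n_g_block))
        members_c = sorted(chem_pool.pop() for _ in range(n_c_block))
        members_d = sorted(disease_pool.pop() for _ in range(n_d_block))
        members = members_g + members_c + members_d
        clusters.append(members)
        for m in members:
            block_of[m] = members
        admissible: list[tuple[str, tuple[str, str]]] = []
        for i, x in enumerate(members_g):
            for y in members_g[i + 1 :]:
                admissible.append(("GG", tuple(sorted((x, y)))))
        for c in members_c:
            for g in members_g:
                admissible.append(("CG", (c, g)))
        for d in members_d:
            for g in members_g:
                admissible.append(("DG", (d, g)))
            for c in members_c:
                admissible.append(("DC", (d, c)))
        n_missing = int(round((1.0 - config.planted_within_density) * len(admissible)))
        missing = {pair for _, pair in _balanced_pairs(admissible, n_missing, rng)}
        for cls, pair in admissible:
            if pair in missing:
                continue
            if cls == "GG":
                planted_gg.add(pair)
            elif cls == "CG":
                cg.add(pair)
            elif cls == "DG":
                dg.add(pair)
            else:
                dc.add(pair)

    # planted blocks are kept edge-disjoint from one another: background
    # edges between members of two different blocks are removed so the
    # planted truth stays identifiable by a clustering method
    if len(clusters) > 1:
        def _cross_block(a: str, b: str) -> bool:
            ba, bb = block_of.get(a), block_of.get(b)
            return ba is not None and bb is not None and ba is not bb

        gg = {e for e in gg if not _cross_block(*e)}
        cg = {e for e in cg if not _cross_block(*e)}
        dg = {e for e in dg if not _cross_block(*e)}
        dc = {e for e in dc if not _cross_block(*e)}

    gg |= planted_gg

    # guaranteed disease anchor for planted members (the disease-context
    # filter would otherwise delete planted structure)
    if diseases:
        dg_genes = {g for _, g in dg}
        dc_chems = {c for _, c in dc}
        for members in clusters:
            for m in members:
                if m.startswith("G") and m not in dg_genes:
                    dg.add((str(rng.choice(diseases)), m))
                    dg_genes.add(m)
                elif m.startswith("C") and m not in dc_chems:
                    dc.add((str(rng.choice(diseases)), m))
                    dc_chems.add(m)

    # withhold planted gene-gene edges into the reference network, again
    # degree-balanced within each block so withholding does not concentrate
    # on a few members
    withheld: list[tuple[str, str]] = []
    for members in clusters:
        block_gg = sorted(e for e in planted_gg if e[0] in members)
        n_withhold = int(round(config.reference_overlap * len(block_gg)))
        withheld.extend(
            pair for _, pair in _balanced_pairs(
                [("GG", e) for e in block_gg], n_withhold, rng
            )
        )
    withheld.sort()
    gg -= set(withheld)
    anchored_genes = sorted({g for _, g in dg})
    noise: list[tuple[str, str]] = []
    if len(anchored_genes) >= 2 and withheld:
        taken = set(withheld) | gg
        attempts = 0
        while len(noise) < len(withheld) and attempts < 50 * len(withheld):
            attempts += 1
            i, j = rng.choice(len(anchored_genes), size=2, replace=False)
            e = tuple(sorted((anchored_genes[i], anchored_genes[j])))
            if e not in taken:
                noise.append(e)
                taken.add(e)
    reference_net = InteractionNetwork()
    for a, b in withheld + noise:
        reference_net.add_edge(a, b, EdgeAnnotation(), kind_a="gene", kind_b="gene")

    # ---- emit tables ----------------------------------------------------
    ppi_rows = [{"gene_a": a, "gene_b": b} for a, b in sorted(gg)]
    for g in genes:
        if rng.random() < _SELF_LOOP_RATE:
            ppi_rows.append({"gene_a": g, "gene_b": g})
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b"])

    cg_rows = []
    type_idx = rng.choice(len(_TYPE_CHOICES), size=len(cg), p=_TYPE_WEIGHTS)
    for (chem, gene), ti in zip(sorted(cg), type_idx):
        types = _TYPE_CHOICES[ti]
        mods = ""
        if rng.random() < 0.1:
            mods = str(rng.choice(_MODS))
        partner = ""
        if rng.random() < config.cooccurrence_rate and len(chems) > 1:
            block = block_of.get(chem)
            block_chems = [c for c in (block or []) if c.startswith("C") and c != chem]
            if block_chems and rng.random() < _BLOCK_PARTNER_RATE:
                partner = str(rng.choice(block_chems))
            else:
                while True:
                    partner = str(rng.choice(chems))
                    if partner != chem:
                        break
        verb = _VERB[types[0]]
        if partner:
            text = f"{chem} co-treated with {partner} {verb} {gene}"
        else:
            text = f"{chem} {verb} {gene}"
        cg_rows.append(
            {
                "chemical": chem,
                "gene": gene,
                "interaction_text": text,
                "raw_types": ";".join(types),
                "modifications": mods,
            }
        )
    # duplicated orientation rows (the reverse-direction query re-reports them)
    dup_mask = rng.random(len(cg_rows)) < _DUPLICATE_ROW_RATE
    cg_rows += [row for row, d in zip(list(cg_rows), dup_mask) if d]
    chem_gene = pd.DataFrame(
        cg_rows, columns=["chemical", "gene", "interaction_text", "raw_types", "modifications"]
    )

    cd_rows = []
    for d, c in sorted(dc):
        r = rng.random()
        if r < config.therapeutic_fraction * 0.8:
            ev = "therapeutic"
        elif r < config.therapeutic_fraction:
            ev = "both"
        else:
            ev = "marker/mechanism"
        cd_rows.append({"chemical": c, "disease": d, "direct_evidence": ev})
    chem_disease = pd.DataFrame(cd_rows, columns=["chemical", "disease", "direct_evidence"])

    gd_rows = []
    for d, g in sorted(dg):
        ev = "marker/mechanism" if rng.random() < 0.85 else "therapeutic"
        gd_rows.append({"gene": g, "disease": d, "direct_evidence": ev})
    gene_disease = pd.DataFrame(gd_rows, columns=["gene", "disease", "direct_evidence"])

    tables = RawInteractionTables(chem_gene, chem_disease, gene_disease, ppi)
    truth = {"clusters": [sorted(c) for c in clusters], "withheld_edges": withheld}
    return SyntheticBundle(tables, truth, reference_net, diseases, config)


def empirical_density(bundle: SyntheticBundle) -> dict[str, float]:
    """Observed per-class link density (distinct pairs / possible pairs)."""
    cfg = bundle.config
    t = bundle.tables
    gg_pairs = {
        tuple(sorted((a, b))) for a, b in zip(t.ppi["gene_a"], t.ppi["gene_b"]) if a != b
    }
    cg_pairs = set(zip(t.chem_gene["chemical"], t.chem_gene["gene"]))
    dg_pairs = set(zip(t.gene_disease["gene"], t.gene_disease["disease"]))
    dc_pairs = set(zip(t.chem_disease["chemical"], t.chem_disease["disease"]))

    def _ratio(count: int, possible: float) -> float:
        return count / possible if possible else math.nan

    return {
        "gene-gene": _ratio(len(gg_pairs), cfg.n_genes * (cfg.n_genes - 1) / 2),
        "gene-chemical": _ratio(len(cg_pairs), cfg.n_genes * cfg.n_chemicals),
        "disease-gene": _ratio(len(dg_pairs), cfg.n_genes * cfg.n_diseases),
        "disease-chemical": _ratio(len(dc_pairs), cfg.n_chemicals * cfg.n_diseases),
    }
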