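"""Construction of the whole and therapeutic networks from raw tables.

Input is four curated-database-style tables: chemical-gene interactions with
free-text interaction descriptions, chemical-disease and gene-disease
associations with a DirectEvidence flag, and a binary protein-protein
interaction table.  The construction rules are:

* restrict to a disease context (a list of diseases of interest) -- an
  interaction is kept when at least one endpoint has a direct curated link to
  a listed disease;
* collapse the two query orientations of chemical-gene interactions into
  undirected edges (type union);
* derive chemical-chemical edges from co-occurrence of a second chemical in
  the free text of a chemical-gene interaction, typed like the host
  interaction;
* the therapeutic network keeps only chemicals with at least one therapeutic
  disease indication, the genes linked to those chemicals, all diseases, and
  adds the co-occurrence chemical-chemical edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    EdgeAnnotation,
    InteractionNetwork,
    NetworkError,
    TripleRecord,
    _split,
)

__all__ = [
    "RawInteractionTables",
    "BuildReport",
    "filter_to_disease_context",
    "dedup_bidirectional",
    "infer_chemical_chemical",
    "build_whole_network",
    "build_therapeutic_network",
    "load_disease_list",
]

DIRECT_EVIDENCE_VALUES = frozenset({"therapeutic", "marker/mechanism", "both", "none"})
#: DirectEvidence values that certify a curated link (``none`` rows are
#: inferred, non-curated associations and never create edges)
_CURATED = frozenset({"therapeutic", "marker/mechanism", "both"})
_THERAPEUTIC = frozenset({"therapeutic", "both"})

_EVIDENCE_TYPES = {
    "therapeutic": frozenset({"therapeutic"}),
    "marker/mechanism": frozenset({"marker/mechanism"}),
    "both": frozenset({"therapeutic", "marker/mechanism"}),
}

TABLE_FILES = {
    "chem_gene": "chem_gene.tsv",
    "chem_disease": "chem_disease.tsv",
    "gene_disease": "gene_disease.tsv",
    "ppi": "ppi.tsv",
}

_TABLE_COLUMNS = {
    "chem_gene": ["chemical", "gene", "interaction_text", "raw_types", "modifications"],
    "chem_disease": ["chemical", "disease", "direct_evidence"],
    "gene_disease": ["gene", "disease", "direct_evidence"],
    "ppi": ["gene_a", "gene_b"],
}


@dataclass
class RawInteractionTables:
    """The four raw input tables, as data frames with fixed columns."""

    chem_gene: pd.DataFrame
    chem_disease: pd.DataFrame
    gene_disease: pd.DataFrame
    ppi: pd.DataFrame

    def validate(self) -> "RawInteractionTables":
        for name, cols in _TABLE_COLUMNS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns and c not in ("modifications",)]
            if missing:
                raise NetworkError(f"table {name!r} lacks columns {missing}")
            for col in cols[:2]:
                vals = df[col].astype(str).str.strip()
                if (vals == "").any():
                    raise NetworkError(f"table {name!r} has empty {col!r} values")
        for name in ("chem_disease", "gene_disease"):
            ev = getattr(self, name)["direct_evidence"]
            bad = set(ev.unique()) - set(DIRECT_EVIDENCE_VALUES)
            if bad:
                raise NetworkError(f"table {name!r} has unknown DirectEvidence {sorted(bad)}")
        return self

    def copy(self) -> "RawInteractionTables":
        return RawInteractionTables(
            self.chem_gene.copy(),
            self.chem_disease.copy(),
            self.gene_disease.copy(),
            self.ppi.copy(),
        )

    @classmethod
    def read_dir(cls, directory: str | Path) -> "RawInteractionTables":
        directory = Path(directory)
        frames = {}
        for name, fname in TABLE_FILES.items():
            path = directory / fname
            if not path.exists():
                raise NetworkError(f"missing input table {path}")
            frames[name] = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        return cls(**frames).validate()

    def write_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, fname in TABLE_FILES.items():
            getattr(self, name).to_csv(directory / fname, sep="\t", index=False)


@dataclass
class BuildReport:
    """Counts recorded while building a network."""

    n_directed_chem_gene: int = 0
    n_unique_after_dedup: int = 0
    n_chem_chem_inferred: int = 0
    filtered_node_counts: dict = field(default_factory=dict)


def load_disease_list(path: str | Path) -> set[str]:
    """One disease name per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def _curated_links(df: pd.DataFrame, entity_col: str, diseases: set[str]) -> pd.DataFrame:
    return df[df["disease"].isin(diseases) & df["direct_evidence"].isin(_CURATED)]


def filter_to_disease_context(
    tables: RawInteractionTables, diseases: set[str]
) -> RawInteractionTables:
    """Restrict the raw tables to the disease context.

    Entities with a direct curated link to a listed disease anchor the
    context.  A chemical-gene row is kept when at least one endpoint is
    anchored; retained entities are the anchored ones plus the partners pulled
    in through kept chemical-gene rows.  A protein-protein row is kept when
    both genes are retained and at least one of the pair is anchored.
    Disease-association rows are kept for retained entities and listed
    diseases only.
    """
    if not diseases:
        raise NetworkError("the disease context must name at least one disease")
    tables.validate()
    anchored_genes = set(_curated_links(tables.gene_disease, "gene", diseases)["gene"])
    anchored_chems = set(_curated_links(tables.chem_disease, "chemical", diseases)["chemical"])

    cg = tables.chem_gene
    keep_cg = cg["chemical"].isin(anchored_chems) | cg["gene"].isin(anchored_genes)
    cg = cg[keep_cg]

    retained_genes = anchored_genes | set(cg["gene"])
    retained_chems = anchored_chems | set(cg["chemical"])

    ppi = tables.ppi
    keep_ppi = (
        ppi["gene_a"].isin(retained_genes)
        & ppi["gene_b"].isin(retained_genes)
        & (ppi["gene_a"].isin(anchored_genes) | ppi["gene_b"].isin(anchored_genes))
    )
    ppi = ppi[keep_ppi]

    gd = tables.gene_disease
    gd = gd[gd["gene"].isin(retained_genes) & gd["disease"].isin(diseases)]
    cd = tables.chem_disease
    cd = cd[cd["chemical"].isin(retained_chems) & cd["disease"].isin(diseases)]

    return RawInteractionTables(
        cg.reset_index(drop=True),
        cd.reset_index(drop=True),
        gd.reset_index(drop=True),
        ppi.reset_index(drop=True),
    )


def dedup_bidirectional(chem_gene: pd.DataFrame) -> tuple[pd.DataFrame, BuildReport]:
    """Collapse duplicated chemical-gene / gene-chemical query orientations.

    Rows with the same (chemical, gene) pair merge into one undirected edge:
    interaction types and modifications union, interaction texts concatenate.
    The report records the before/after row counts.
    """
    report = BuildReport(n_directed_chem_gene=len(chem_gene))
    if chem_gene.empty:
        report.n_unique_after_dedup = 0
        return chem_gene.copy(), report

    def _agg(group: pd.DataFrame) -> pd.Series:
        raw = frozenset().union(*(_split(t) for t in group.get("raw_types", pd.Series([""] * len(group)))))
        mods = frozenset()
        if "modifications" in group:
            mods = frozenset().union(*(_split(t) for t in group["modifications"]))
        texts = [t for t in group.get("interaction_text", pd.Series([""] * len(group))) if t]
        return pd.Series(
            {
                "interaction_text": " | ".join(dict.fromkeys(texts)),
                "raw_types": ";".join(sorted(raw)),
                "modifications": ";".join(sorted(mods)),
            }
        )

    unique = (
        chem_gene.groupby(["chemical", "gene"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    report.n_unique_after_dedup = len(unique)
    return unique, report


def _vocabulary_pattern(vocabulary: Iterable[str]) -> re.Pattern | None:
    names = sorted({v for v in vocabulary if v}, key=lambda s: (-len(s), s))
    if not names:
        return None
    body = "|".join(re.escape(n) for n in names)
    # word-boundary delimited, case-insensitive, longest vocabulary name first
    return re.compile(rf"(?<!\w)(?:{body})(?!\w)", re.IGNORECASE)


def infer_chemical_chemical(
    chem_gene: pd.DataFrame, vocabulary: Iterable[str]
) -> list[TripleRecord]:
    """Chemical-chemical edges from co-occurrence in interaction text.

    For each chemical-gene row whose free text mentions a second chemical
    from ``vocabulary`` (exact longest match, word-boundary delimited,
    case-insensitive), emit an undirected chemical-chemical edge typed like
    the host chemical-gene interaction.  Duplicate pairs merge their types.
    """
    vocab = {v.lower(): v for v in vocabulary if v}
    pattern = _vocabulary_pattern(vocab.values())
    if pattern is None or chem_gene.empty:
        return []
    merged: dict[tuple[str, str], EdgeAnnotation] = {}
    texts = chem_gene.get("interaction_text")
    if texts is None:
        return []
    for host, text, raw in zip(
        chem_gene["chemical"], texts, chem_gene.get("raw_types", [""] * len(chem_gene))
    ):
        if not text:
            continue
        ann = EdgeAnnotation(_split(raw))
        for m in pattern.finditer(text):
            other = vocab[m.group(0).lower()]
            if other == host:
                continue
            key = tuple(sorted((host, other)))
            merged[key] = merged[key].merge(ann) if key in merged else ann
    return [TripleRecord(a, b, ann) for (a, b), ann in sorted(merged.items())]


def _add_disease_edges(net: InteractionNetwork, df: pd.DataFrame, entity_col: str, kind: str) -> None:
    for _, row in df.iterrows():
        if row["direct_evidence"] not in _CURATED:
            continue
        ann = EdgeAnnotation(_EVIDENCE_TYPES[row["direct_evidence"]])
        net.add_edge(row[entity_col], row["disease"], ann, kind_a=kind, kind_b="disease")


def _add_chem_gene_edges(net: InteractionNetwork, cg: pd.DataFrame) -> None:
    mods_col = cg["modifications"] if "modifications" in cg else [""] * len(cg)
    for chem, gene, raw, mods in zip(cg["chemical"], cg["gene"], cg["raw_types"], mods_col):
        ann = EdgeAnnotation(_split(raw), _split(mods))
        net.add_edge(chem, gene, ann, kind_a="chemical", kind_b="gene")


def _add_ppi_edges(net: InteractionNetwork, ppi: pd.DataFrame) -> None:
    # protein-protein links are untyped; self-interactions are retained
    for a, b in zip(ppi["gene_a"], ppi["gene_b"]):
        net.add_edge(a, b, EdgeAnnotation(), kind_a="gene", kind_b="gene")


def build_whole_network(
    tables: RawInteractionTables,
    diseases: set[str],
    return_report: bool = False,
) -> InteractionNetwork | tuple[InteractionNetwork, BuildReport]:
    """Whole disease-context network: disease-gene, disease-chemical,
    chemical-gene (deduplicated) and gene-gene edges.  No chemical-chemical
    edges are present in this network."""
    filtered = filter_to_disease_context(tables, diseases)
    cg, report = dedup_bidirectional(filtered.chem_gene)
    net = InteractionNetwork()
    _add_chem_gene_edges(net, cg)
    _add_ppi_edges(net, filtered.ppi)
    _add_disease_edges(net, filtered.gene_disease, "gene", "gene")
    _add_disease_edges(net, filtered.chem_disease, "chemical", "chemical")
    report.filtered_node_counts = {
        k: len(net.nodes_of_kind(k)) for k in ("gene", "chemical", "disease")
    }
    if return_report:
        return net, report
    return net


def build_therapeutic_network(
    tables: RawInteractionTables,
    diseases: set[str],
    return_report: bool = False,
) -> InteractionNetwork | tuple[InteractionNetwork, BuildReport]:
    """Therapeutic sub-network.

    Chemicals are retained iff they carry at least one therapeutic disease
    indication (DirectEvidence ``therapeutic`` or ``both``) to a listed
    disease; genes are retained iff they interact with a retained chemical;
    all diseases of the whole network are retained.  Chemical-chemical
    co-occurrence edges between retained chemicals are added.
    """
    filtered = filter_to_disease_context(tables, diseases)
    cd = filtered.chem_disease
    therapeutic_chems = set(cd[cd["direct_evidence"].isin(_THERAPEUTIC)]["chemical"])

    cg, report = dedup_bidirectional(filtered.chem_gene)
    cg = cg[cg["chemical"].isin(therapeutic_chems)]
    retained_genes = set(cg["gene"])

    # disease node set matches the whole network: every listed disease with a
    # curated association among the context entities stays, linked or not
    gd_cur = filtered.gene_disease[filtered.gene_disease["direct_evidence"].isin(_CURATED)]
    cd_cur = cd[cd["direct_evidence"].isin(_CURATED)]
    whole_diseases = set(gd_cur["disease"]) | set(cd_cur["disease"])

    net = InteractionNetwork()
    for d in sorted(whole_diseases):
        net.add_node(d, "disease")
    _add_chem_gene_edges(net, cg)
    ppi = filtered.ppi
    _add_ppi_edges(net, ppi[ppi["gene_a"].isin(retained_genes) & ppi["gene_b"].isin(retained_genes)])
    gd = filtered.gene_disease
    _add_disease_edges(net, gd[gd["gene"].isin(retained_genes)], "gene", "gene")
    _add_disease_edges(net, cd[cd["chemical"].isin(therapeutic_chems)], "chemical", "chemical")

    cc = infer_chemical_chemical(cg, therapeutic_chems)
    for rec in cc:
        net.add_edge(rec.a, rec.b, rec.annotation, kind_a="chemical", kind_b="chemical")
    report.n_chem_chem_inferred = len(cc)
    report.filtered_node_counts = {
        k: len(net.nodes_of_kind(k)) for k in ("gene", "chemical", "disease")
    }
    if return_report:
        return net, report
    return net
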