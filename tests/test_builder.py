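"""Construction rules: disease-context filtering, deduplication,
co-occurrence inference, and the whole/therapeutic network builders."""

import pandas as pd
import pytest

from respnet.builder import (
    RawInteractionTables,
    build_therapeutic_network,
    build_whole_network,
    dedup_bidirectional,
    filter_to_disease_context,
    infer_chemical_chemical,
)
from respnet.core import NetworkError, edge_class


def _tables(chem_gene=(), chem_disease=(), gene_disease=(), ppi=()):
    return RawInteractionTables(
        chem_gene=pd.DataFrame(
            list(chem_gene),
            columns=["chemical", "gene", "interaction_text", "raw_types", "modifications"],
        ),
        chem_disease=pd.DataFrame(
            list(chem_disease), columns=["chemical", "disease", "direct_evidence"]
        ),
        gene_disease=pd.DataFrame(
            list(gene_disease), columns=["gene", "disease", "direct_evidence"]
        ),
        ppi=pd.DataFrame(list(ppi), columns=["gene_a", "gene_b"]),
    )


class TestDiseaseContextFilter:
    def test_six_row_rule_trace(self):
        # g1 is disease-anchored; c1 is not; g2 has no links at all
        tables = _tables(
            chem_gene=[
                ("c1", "g1", "", "increases", ""),  # kept: g1 anchored
                ("c2", "g3", "", "affects", ""),  # dropped: neither anchored
            ],
            gene_disease=[("g1", "d1", "marker/mechanism")],
            chem_disease=[("c9", "d9", "therapeutic")],  # d9 not in context
            ppi=[("g1", "g2"), ("g1", "g1")],
        )
        out = filter_to_disease_context(tables, {"d1"})
        assert list(zip(out.chem_gene["chemical"], out.chem_gene["gene"])) == [("c1", "g1")]
        # g2 has no disease link and no chem-gene route: its PPI row drops
        assert list(zip(out.ppi["gene_a"], out.ppi["gene_b"])) == [("g1", "g1")]
        assert out.chem_disease.empty
        assert len(out.gene_disease) == 1

    def test_all_entities_anchored_is_identity(self):
        tables = _tables(
            chem_gene=[("c1", "g1", "", "affects", "")],
            gene_disease=[("g1", "d1", "marker/mechanism")],
            chem_disease=[("c1", "d1", "therapeutic")],
            ppi=[("g1", "g1")],
        )
        out = filter_to_disease_context(tables, {"d1"})
        for name in ("chem_gene", "chem_disease", "gene_disease", "ppi"):
            pd.testing.assert_frame_equal(
                getattr(out, name).reset_index(drop=True),
                getattr(tables, name).reset_index(drop=True),
            )

    def test_empty_disease_set_is_error(self):
        with pytest.raises(NetworkError):
            filter_to_disease_context(_tables(), set())

    def test_ppi_needs_one_directly_anchored_gene(self):
        # g3 and g4 both retained through chem-gene routes, but neither has a
        # direct disease link: their mutual PPI row drops
        tables = _tables(
            chem_gene=[("c1", "g3", "", "affects", ""), ("c1", "g4", "", "affects", "")],
            chem_disease=[("c1", "d1", "therapeutic")],
            ppi=[("g3", "g4")],
        )
        out = filter_to_disease_context(tables, {"d1"})
        assert len(out.chem_gene) == 2
        assert out.ppi.empty


class TestDedupBidirectional:
    def test_reciprocal_pair_collapses(self):
        df = _tables(
            chem_gene=[
                ("c1", "g1", "t1", "increases", ""),
                ("c1", "g1", "t2", "decreases", ""),
            ]
        ).chem_gene
        unique, report = dedup_bidirectional(df)
        assert report.n_directed_chem_gene == 2
        assert report.n_unique_after_dedup == 1
        assert set(unique.iloc[0]["raw_types"].split(";")) == {"decreases", "increases"}

    def test_six_rows_two_reciprocal_two_singleton(self):
        rows = [
            ("c1", "g1", "", "increases", ""),
            ("c1", "g1", "", "increases", ""),
            ("c2", "g2", "", "decreases", ""),
            ("c2", "g2", "", "decreases", ""),
            ("c3", "g3", "", "affects", ""),
            ("c4", "g4", "", "affects", ""),
        ]
        unique, report = dedup_bidirectional(_tables(chem_gene=rows).chem_gene)
        assert report.n_directed_chem_gene == 6
        assert len(unique) == 4

    def test_idempotent(self):
        rows = [
            ("c1", "g1", "a", "increases", ""),
            ("c1", "g1", "b", "decreases", "oxidation"),
            ("c2", "g1", "c", "affects", ""),
        ]
        once, r1 = dedup_bidirectional(_tables(chem_gene=rows).chem_gene)
        twice, r2 = dedup_bidirectional(once)
        pd.testing.assert_frame_equal(once, twice)
        assert r1.n_unique_after_dedup == r2.n_directed_chem_gene == r2.n_unique_after_dedup

    def test_empty_input(self):
        unique, report = dedup_bidirectional(_tables().chem_gene)
        assert unique.empty and report.n_unique_after_dedup == 0


class TestCooccurrence:
    def test_secondary_chemical_in_text(self):
        df = _tables(
            chem_gene=[
                ("aspirinX", "G", "aspirinX inhibits reaction of chemB with G", "decreases", "")
            ]
        ).chem_gene
        records = infer_chemical_chemical(df, {"aspirinX", "chemB"})
        assert len(records) == 1
        rec = records[0]
        assert {rec.a, rec.b} == {"aspirinX", "chemB"}
        assert rec.annotation.raw_types == {"decreases"}

    def test_no_mentions_gives_empty(self):
        df = _tables(chem_gene=[("c1", "g1", "c1 affects g1", "affects", "")]).chem_gene
        assert infer_chemical_chemical(df, {"c1", "c2"}) == []

    def test_duplicate_pairs_merge_to_mixed(self):
        rows = [
            ("c1", "g1", "c1 with c2 increases g1", "increases", ""),
            ("c1", "g2", "c1 with c2 decreases g2", "decreases", ""),
        ]
        records = infer_chemical_chemical(_tables(chem_gene=rows).chem_gene, {"c1", "c2"})
        assert len(records) == 1
        assert records[0].annotation.raw_types == {"increases", "decreases"}
        assert records[0].annotation.polarity == "mixed"

    def test_word_boundary_and_case(self):
        rows = [("c1", "g1", "co-treatment with CHEMB2 (not chemB22) affects g1", "affects", "")]
        records = infer_chemical_chemical(_tables(chem_gene=rows).chem_gene, {"c1", "chemB2"})
        assert [{r.a, r.b} for r in records] == [{"c1", "chemB2"}]


_THERAPEUTIC_FIXTURE = dict(
    chem_gene=[
        ("cT", "g1", "cT with cT2 increases g1", "increases", ""),
        ("cT2", "g1", "", "affects", ""),
        ("cM", "g2", "", "decreases", ""),  # cM has only marker/mechanism evidence
    ],
    chem_disease=[
        ("cT", "d1", "therapeutic"),
        ("cT2", "d1", "both"),
        ("cM", "d1", "marker/mechanism"),
    ],
    gene_disease=[("g1", "d1", "marker/mechanism"), ("g2", "d1", "marker/mechanism")],
    ppi=[("g1", "g2"), ("g1", "g1")],
)


class TestBuildNetworks:
    def test_whole_network_recount(self, default_bundle):
        tables = default_bundle.tables
        diseases = set(default_bundle.diseases)
        net, report = build_whole_network(tables, diseases, return_report=True)
        # recount: every edge class matches an independent pass over the edges
        classes = {}
        for a, b, _ in net.edges():
            cls = edge_class(net.kind(a), net.kind(b))
            classes[cls] = classes.get(cls, 0) + 1
        assert classes.get("chemical-chemical", 0) == 0
        assert sum(classes.values()) == net.number_of_edges()
        assert report.n_unique_after_dedup <= report.n_directed_chem_gene
        assert report.filtered_node_counts["gene"] == len(net.nodes_of_kind("gene"))

    def test_whole_requires_disease_context(self):
        with pytest.raises(NetworkError):
            build_whole_network(_tables(**_THERAPEUTIC_FIXTURE), set())

    def test_unanchored_chemicals_absent(self):
        tables = _tables(
            chem_gene=[("c1", "g9", "", "affects", "")],  # neither endpoint anchored
            gene_disease=[("g1", "d1", "marker/mechanism")],
        )
        net = build_whole_network(tables, {"d1"})
        assert net.nodes_of_kind("chemical") == []

    def test_therapeutic_excludes_marker_only_chemicals(self):
        net = build_therapeutic_network(_tables(**_THERAPEUTIC_FIXTURE), {"d1"})
        assert net.nodes_of_kind("chemical") == ["cT", "cT2"]
        assert not net.has_edge("cM", "g2")

    def test_gene_without_therapeutic_chemical_dropped(self):
        net = build_therapeutic_network(_tables(**_THERAPEUTIC_FIXTURE), {"d1"})
        # g2 interacts only with the excluded chemical cM
        assert net.nodes_of_kind("gene") == ["g1"]

    def test_cooccurrence_creates_chemical_chemical_edge(self):
        net = build_therapeutic_network(_tables(**_THERAPEUTIC_FIXTURE), {"d1"})
        assert net.has_edge("cT", "cT2")
        assert edge_class("chemical", "chemical") == "chemical-chemical"

    def test_therapeutic_keeps_all_whole_diseases(self, default_bundle, whole_net, therapeutic_net):
        assert therapeutic_net.nodes_of_kind("disease") == whole_net.nodes_of_kind("disease")

    def test_therapeutic_subgraph_of_whole_except_cc(self, whole_net, therapeutic_net):
        for a, b, _ in therapeutic_net.edges():
            cls = edge_class(therapeutic_net.kind(a), therapeutic_net.kind(b))
            if cls == "chemical-chemical":
                continue
            assert whole_net.has_edge(a, b)

    def test_every_retained_entity_near_a_disease(self, whole_net):
        # construction invariant: every gene/chemical is within 2 steps of a
        # disease in the whole network
        import networkx as nx

        g = whole_net.simple_graph()
        diseases = set(whole_net.nodes_of_kind("disease"))
        for v in whole_net.nodes_of_kind("gene") + whole_net.nodes_of_kind("chemical"):
            dists = nx.single_source_shortest_path_length(g, v, cutoff=2)
            assert diseases & set(dists), f"{v} has no disease within 2 steps"
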