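import networkx as nx
import pandas as pd
import pytest

from netpharm.io import ComponentRecord, GeneSetCollection, PathogenicGene
from netpharm.network import (
    assemble_ctpd,
    bin_evidence_profile,
    build_ct_network,
    extract_tp,
    gene_nodes,
)


def comp(cid):
    return ComponentRecord(cid, cid, 100.0, 1, 1, 1, 1.0, 50.0)


def edges(pairs):
    return pd.DataFrame(pairs, columns=["source", "target"])


class TestBuildCT:
    def test_disjoint_targets_counts(self):
        g = build_ct_network(
            [comp("c1"), comp("c2")],
            edges([("c1", t) for t in "ABC"] + [("c2", t) for t in "DEF"]),
        )
        ct = [e for *e, d in g.edges(data=True) if d["etype"] == "CT"]
        assert len(ct) == 6
        assert g.degree("c1") == 3 and g.degree("c2") == 3
        assert all(g.nodes[t]["nc"] == 1 for t in "ABCDEF")

    def test_isolated_component(self):
        g = build_ct_network([comp("c1")], edges([]))
        assert g.degree("c1") == 0 and g.number_of_nodes() == 1

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            build_ct_network([comp("c1")], edges([("ghost", "A")]))

    def test_degrees_match_generator_ledger(self, bundle, pipeline_state):
        g = pipeline_state["ct"].groupby("source").size()
        for cid, n in bundle.ledger["ct_degree_per_component"].items():
            if cid in g.index:  # screened-out violators lose their edges
                assert g[cid] == n


class TestAssemble:
    def setup_method(self):
        ct = build_ct_network([comp("c1")], edges([("c1", "A"), ("c1", "B")]))
        self.ctpd = assemble_ctpd(
            ct,
            edges([("A", "B"), ("B", "C")]),
            [PathogenicGene("B", 2), PathogenicGene("C", 5)],
            disease_label="dep",
        )

    def test_roles_union_and_edge_types(self):
        assert self.ctpd.nodes["B"]["roles"] == {"target", "pathogenic"}
        types = sorted(d["etype"] for *_, d in self.ctpd.edges(data=True))
        assert types.count("PPI") == 2 and types.count("GD") == 2 and types.count("CT") == 2

    def test_disease_node_only_touches_gd(self):
        assert all(
            self.ctpd.edges[e]["etype"] == "GD" for e in self.ctpd.edges("dep")
        )
        assert self.ctpd.degree("dep") == 2

    def test_empty_ppi_gives_ct_plus_gd_star(self):
        ct = build_ct_network([comp("c1")], edges([("c1", "A")]))
        g = assemble_ctpd(ct, edges([]), [PathogenicGene("P", 1)], "d")
        assert sorted(d["etype"] for *_, d in g.edges(data=True)) == ["CT", "GD"]

    def test_unmatched_ppi_rows_not_fatal(self):
        ct = build_ct_network([comp("c1")], edges([("c1", "A")]))
        g = assemble_ctpd(ct, edges([("X", "Y")]), [], "d")
        assert "X" not in g and "Y" not in g

    def test_roles_monotone_under_layering(self, bundle, pipeline_state):
        # adding PPI + pathogenic layers never removes the target role
        ctpd = pipeline_state["ctpd"]
        ct_targets = {
            n
            for n, d in build_ct_network(
                pipeline_state["kept"], pipeline_state["ct"]
            ).nodes(data=True)
            if "target" in d["roles"]
        }
        assert all("target" in ctpd.nodes[t]["roles"] for t in ct_targets)

    def test_nc_conservation(self, pipeline_state):
        ctpd = pipeline_state["ctpd"]
        n_ct = sum(1 for *_, d in ctpd.edges(data=True) if d["etype"] == "CT")
        total_nc = sum(
            d.get("nc", 0) for _, d in ctpd.nodes(data=True) if "target" in d["roles"]
        )
        assert total_nc == n_ct


class TestExtractTP:
    def test_keeps_gene_layer_and_ppi_only(self):
        ct = build_ct_network([comp("c1")], edges([("c1", "A"), ("c1", "B")]))
        ctpd = assemble_ctpd(
            ct, edges([("A", "B"), ("B", "C")]), [PathogenicGene("B", 2), PathogenicGene("C", 5)], "d"
        )
        tp = extract_tp(ctpd)
        assert sorted(tp.nodes) == ["A", "B", "C"]
        assert sorted(map(sorted, tp.edges)) == [["A", "B"], ["B", "C"]]

    def test_no_ppi_gives_edgeless_graph(self):
        ct = build_ct_network([comp("c1")], edges([("c1", "A")]))
        tp = extract_tp(assemble_ctpd(ct, edges([]), [PathogenicGene("P", 1)], "d"))
        assert tp.number_of_edges() == 0 and sorted(tp.nodes) == ["A", "P"]

    def test_errors_without_gene_layer(self):
        g = nx.Graph()
        g.add_node("c1", roles={"component"})
        with pytest.raises(ValueError, match="no gene layer"):
            extract_tp(g)

    def test_node_set_is_target_union_pathogenic(self, pipeline_state):
        ctpd = pipeline_state["ctpd"]
        tp = pipeline_state["tp"]
        assert sorted(tp.nodes) == gene_nodes(ctpd)

    def test_second_extraction_is_identity(self, pipeline_state):
        tp = pipeline_state["tp"]
        again = extract_tp(tp)
        assert sorted(again.nodes) == sorted(tp.nodes)
        assert sorted(map(sorted, again.edges)) == sorted(map(sorted, tp.edges))


class TestEvidenceProfile:
    def test_counts_per_bin(self):
        genes = [PathogenicGene("a", 1), PathogenicGene("b", 1), PathogenicGene("c", 3)]
        coll = GeneSetCollection("x", {"t": ("d", frozenset({"c"}))})
        prof = bin_evidence_profile(genes, coll, [(1, 2), (2, float("inf"))])
        assert prof["n_genes"].tolist() == [2, 1]
        assert prof["mean_terms"].tolist() == [0.0, 1.0]

    def test_empty_collection_means_zero(self):
        genes = [PathogenicGene("a", 1)]
        prof = bin_evidence_profile(genes, GeneSetCollection("x"), [(1, float("inf"))])
        assert prof["mean_terms"].tolist() == [0.0]

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            bin_evidence_profile([], GeneSetCollection("x"), [(1, 3), (2, float("inf"))])
        with pytest.raises(ValueError, match="cover"):
            bin_evidence_profile([], GeneSetCollection("x"), [(1, 5)])

    def test_planted_term_membership_means(self, bundle):
        # every hub-module term contains the hub itself, so a hub's term
        # count is at least 1 and matches a direct recount
        counts = bundle.collection.terms_per_gene()
        prof = bin_evidence_profile(
            bundle.pathogenic, bundle.collection, [(1, 3), (3, float("inf"))]
        )
        assert prof["n_genes"].sum() == len(bundle.pathogenic)
        for _, row in prof.iterrows():
            members = [
                g for g in bundle.pathogenic if row["bin_lo"] <= g.nv < row["bin_hi"]
            ]
            expect = (
                sum(counts.get(g.symbol, 0) for g in members) / len(members)
                if members
                else 0.0
            )
            assert row["mean_terms"] == pytest.approx(expect)
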