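import networkx as nx
import numpy as np
import pytest

from netpharm.importance import (
    baseline_centralities,
    categorize_nodes,
    effective_diameter,
    extract_eis,
    node_importance,
)
from oracles import diameter_oracle, im_oracle


def im_of(graph):
    return node_importance(graph, with_baselines=False).scores["im"]


class TestEffectiveDiameter:
    def test_path_graph(self):
        assert effective_diameter(nx.path_graph(3)) == 2

    def test_disconnected_takes_max_over_components(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert effective_diameter(g) == 1
        g.add_edge("d", "e")
        assert effective_diameter(g) == 2

    def test_isolated_nodes_contribute_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        assert effective_diameter(g) == 1

    def test_single_node_undefined(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError, match="diameter"):
            effective_diameter(g)

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = nx.gnp_random_graph(30, 0.08, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            assert effective_diameter(g) == diameter_oracle(g)


class TestNodeImportance:
    def test_path_center(self):
        im = im_of(nx.path_graph(["a", "b", "c"]))
        assert im["b"] == pytest.approx(1 / 6)
        assert im["a"] == im["c"] == 0.0

    def test_star_center(self):
        g = nx.star_graph(3)  # center 0, three leaves
        im = im_of(g)
        assert im[0] == pytest.approx(0.25)
        assert all(im[leaf] == 0.0 for leaf in (1, 2, 3))

    def test_triangle_all_zero(self):
        assert (im_of(nx.complete_graph(3)) == 0).all()

    def test_requires_three_nodes_and_an_edge(self):
        with pytest.raises(ValueError):
            node_importance(nx.path_graph(2))
        g = nx.empty_graph(4)
        with pytest.raises(ValueError):
            node_importance(g)

    @pytest.mark.parametrize("n,p,seed", [(8, 0.3, 0), (8, 0.5, 1), (12, 0.25, 2), (20, 0.15, 3)])
    def test_matches_enumeration_oracle(self, n, p, seed):
        g = nx.gnp_random_graph(n, p, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        expect = im_oracle(g)
        got = im_of(g)
        for v in g.nodes:
            assert got[v] == pytest.approx(expect[v], abs=1e-12)

    def test_zero_iff_no_transit_betweenness(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = nx.gnp_random_graph(9, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            table = node_importance(g)
            bt = nx.betweenness_centrality(g, normalized=False)
            for v in g.nodes:
                assert (table.scores.loc[v, "im"] == 0) == (bt[v] == 0)

    def test_first_factor_bounds_imply_im_ceiling(self):
        # transit paths have length in [2, eff_d], so im <= (eff_d-1)/eff_d
        g = nx.gnp_random_graph(15, 0.2, seed=5)
        table = node_importance(g)
        d = table.eff_diameter
        assert (table.scores["im"] <= (d - 1) / d + 1e-12).all()
        assert (table.scores["im"] >= 0).all()

    def test_disconnected_extra_component_shifts_only_via_diameter_and_n(self):
        g = nx.Graph([("c", "l1"), ("c", "l2"), ("c", "l3")])
        h = g.copy()
        h.add_edge("x", "y")  # disjoint edge: n 4->6, eff_d unchanged
        im_g, im_h = im_of(g), im_of(h)
        # transit structure of the star is untouched; only the n(n-1)/2
        # normalization dilutes the center's score
        assert im_h["c"] == pytest.approx(im_g["c"] * (4 * 3) / (6 * 5))
        assert im_h["x"] == im_h["y"] == 0.0
        assert im_oracle(h)["c"] == pytest.approx(im_h["c"], abs=1e-12)


class TestBaselines:
    def test_triangle_degree_and_clustering(self):
        b = baseline_centralities(nx.complete_graph(3))
        assert (b["degree"] == 2).all() and (b["clustering"] == 1.0).all()

    def test_star_center_betweenness(self):
        b = baseline_centralities(nx.star_graph(3))
        assert b.loc[0, "betweenness"] == pytest.approx(1.0)

    def test_neighborhood_connectivity_brute_force(self):
        g = nx.gnp_random_graph(30, 0.12, seed=9)
        b = baseline_centralities(g)
        for v in g.nodes:
            nbrs = list(g.neighbors(v))
            expect = sum(g.degree(w) for w in nbrs) / len(nbrs) if nbrs else 0.0
            assert b.loc[v, "neighborhood_connectivity"] == pytest.approx(expect)


class TestEIS:
    def test_star_keeps_center_only(self):
        g = nx.star_graph(3)
        table = node_importance(g)
        eis = extract_eis(g, table)
        assert sorted(eis.graph.nodes) == [0]
        assert eis.graph.number_of_edges() == 0

    def test_all_equal_scores_error(self):
        g = nx.complete_graph(4)  # every im is 0
        with pytest.raises(ValueError, match="median"):
            extract_eis(g, node_importance(g))

    def test_ge_mode_keeps_ties(self):
        g = nx.complete_graph(4)
        eis = extract_eis(g, node_importance(g), mode="ge")
        assert sorted(eis.graph.nodes) == [0, 1, 2, 3]

    def test_threshold_monotonicity(self, pipeline_state):
        # strict > median is a subset of >= median
        tp, table = pipeline_state["tp"], pipeline_state["importance"]
        strict = set(extract_eis(tp, table, mode="strict").graph.nodes)
        loose = set(extract_eis(tp, table, mode="ge").graph.nodes)
        assert strict <= loose

    def test_recovers_planted_hubs(self, bundle, pipeline_state):
        hubs = set(bundle.ledger["planted_hubs"])
        got = set(pipeline_state["eis"].graph.nodes)
        assert len(hubs & got) / len(hubs) >= 0.9


class TestCategorize:
    def test_three_way_split(self, toy_tp_graph):
        table = node_importance(toy_tp_graph)
        eis = extract_eis(toy_tp_graph, table)  # B is the only transit node
        cats = categorize_nodes(eis, target_set={"A", "B"}, pathogenic_set={"B", "C"})
        assert cats == {"B": "essential_common"}

    def test_disease_and_component_specific(self, pipeline_state, bundle):
        eis = pipeline_state["eis"]
        targets = {
            n for n, d in pipeline_state["tp"].nodes(data=True) if "target" in d["roles"]
        }
        pathogenic = {p.symbol for p in bundle.pathogenic}
        cats = categorize_nodes(eis, targets, pathogenic)
        assert set(cats) == set(eis.graph.nodes)  # partition covers the EIS
        only_p = [v for v, c in cats.items() if c == "disease_specific"]
        assert all(v in pathogenic and v not in targets for v in only_p)

    def test_uncategorizable_node_is_error(self, toy_tp_graph):
        table = node_importance(toy_tp_graph)
        eis = extract_eis(toy_tp_graph, table)
        with pytest.raises(ValueError, match="neither"):
            categorize_nodes(eis, target_set=set(), pathogenic_set=set())
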