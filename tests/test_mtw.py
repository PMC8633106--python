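import itertools

import networkx as nx
import numpy as np
import pytest

from netpharm.mtw import (
    CascadePath,
    ScoreContext,
    annotate_signaling_graph,
    merge_modules,
    normalize_evidence,
    normalize_regulation,
    retain_cascades,
    score_cascade,
    shortest_cascades,
)
from oracles import min_weight_path_oracle

CTX = ScoreContext(r_avg=0.5, d_avg=0.5, pg_bounds=(0.0, 1.0), tg_bounds=(0.0, 1.0))


def chain_graph(nodes, *, in_tg, in_pg, nv, nc, im):
    g = nx.DiGraph()
    nx.add_path(g, nodes)
    for v in nodes:
        g.nodes[v].update(in_tg=in_tg, in_pg=in_pg, nv=nv, nc=nc, im=im)
    return g


class TestNormalization:
    def test_extremes_and_midpoint(self):
        assert normalize_evidence(11, (1, 11)) == 1.0
        assert normalize_evidence(1, (1, 11)) == 0.0
        assert normalize_evidence(6, (1, 11)) == pytest.approx(0.5)
        assert normalize_regulation(2, (0, 8)) == pytest.approx(0.25)
        assert normalize_regulation(8, (0, 8)) == 1.0

    def test_degenerate_bounds_map_to_zero(self):
        assert normalize_evidence(5, (5, 5)) == 0.0
        assert normalize_regulation(3, (3, 3)) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            normalize_evidence(-1, (0, 5))

    def test_out_of_band_counts_clip_into_unit_interval(self):
        assert normalize_evidence(99, (1, 11)) == 1.0
        assert normalize_regulation(0, (2, 8)) == 0.0


class TestShortestCascades:
    def test_simple_chain(self):
        g = nx.DiGraph([("r", "a"), ("a", "b"), ("b", "t")])
        assert shortest_cascades(g) == [("r", "a", "b", "t")]

    def test_diamond_tie_breaks_lexicographically(self):
        g = nx.DiGraph([("r", "a"), ("a", "t"), ("r", "b"), ("b", "t")])
        assert shortest_cascades(g) == [("r", "a", "t")]

    def test_unreachable_pairs_omitted(self):
        g = nx.DiGraph([("r", "t"), ("r2", "t2")])
        paths = shortest_cascades(g, sources=["r", "r2"], sinks=["t", "t2"])
        assert paths == [("r", "t"), ("r2", "t2")]

    def test_weighted_route_beats_hop_count(self):
        g = nx.DiGraph()
        g.add_edge("r", "t", weight=10.0)
        g.add_edge("r", "m", weight=1.0)
        g.add_edge("m", "t", weight=1.0)
        assert shortest_cascades(g) == [("r", "m", "t")]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_simple_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        order = list(range(10))
        g = nx.DiGraph()
        g.add_nodes_from(order)
        for i, j in itertools.combinations(order, 2):
            if rng.random() < 0.3:
                g.add_edge(i, j, weight=float(rng.integers(1, 6)))
        sources = [n for n in g if g.in_degree(n) == 0 and g.out_degree(n) > 0]
        sinks = [n for n in g if g.out_degree(n) == 0 and g.in_degree(n) > 0]
        if not sources or not sinks:
            pytest.skip("degenerate draw")
        for path in shortest_cascades(g, sources, sinks):
            w = sum(g.edges[u, v]["weight"] for u, v in zip(path, path[1:]))
            assert w == min_weight_path_oracle(g, path[0], path[-1])


class TestScoreCascade:
    def test_all_dual_membership(self):
        g = chain_graph("abc", in_tg=True, in_pg=True, nv=1, nc=1, im=0.1)
        got = score_cascade(tuple("abc"), g, CTX)
        # per-node: 0.1 + 1 + 1 + 0.5 + 0.5 = 3.1
        assert got.raw == pytest.approx(9.3) and got.normalized == pytest.approx(3.1)

    def test_all_outside_both_sets(self):
        g = chain_graph("abc", in_tg=False, in_pg=False, nv=0, nc=0, im=0.0)
        assert score_cascade(tuple("abc"), g, CTX).raw == pytest.approx(-3.0)

    def test_mixed_membership_signs(self):
        g = chain_graph("ab", in_tg=True, in_pg=False, nv=0, nc=1, im=0.0)
        # TG only: im + r + d - r_avg + d_avg = 0 + 0 + 1 - 0.5 + 0.5
        assert score_cascade(("a", "b"), g, CTX).raw == pytest.approx(2.0)
        g2 = chain_graph("ab", in_tg=False, in_pg=True, nv=1, nc=0, im=0.0)
        assert score_cascade(("a", "b"), g2, CTX).raw == pytest.approx(2.0)

    def test_two_node_additivity(self):
        g = chain_graph("ab", in_tg=True, in_pg=True, nv=1, nc=1, im=0.2)
        got = score_cascade(("a", "b"), g, CTX)
        assert got.raw == pytest.approx(2 * (0.2 + 1 + 1 + 0.5 + 0.5))

    def test_concatenation_additivity(self):
        g = chain_graph("abcde", in_tg=True, in_pg=True, nv=1, nc=1, im=0.1)
        full = score_cascade(tuple("abcde"), g, CTX).raw
        left = score_cascade(tuple("abc"), g, CTX).raw
        right = score_cascade(tuple("cde"), g, CTX).raw
        shared = score_cascade(tuple("cd"), g, CTX).raw / 2  # one node's term
        assert full == pytest.approx(left + right - shared)

    def test_missing_attribute_names_node(self):
        g = nx.DiGraph([("a", "b")])
        g.nodes["a"].update(in_tg=True, in_pg=True, nv=1, nc=1, im=0.0)
        with pytest.raises(ValueError, match="'b'"):
            score_cascade(("a", "b"), g, CTX)

    def test_raw_score_bound(self):
        g = chain_graph("abcd", in_tg=True, in_pg=True, nv=1, nc=1, im=0.3)
        got = score_cascade(tuple("abcd"), g, CTX)
        assert got.raw <= 4 * (0.3 + 2 + CTX.r_avg + CTX.d_avg) + 1e-12

    def test_short_path_rejected(self):
        with pytest.raises(ValueError):
            CascadePath(nodes=("only",), raw=0.0, normalized=0.0)


class TestRetain:
    def test_strictly_greater_filter_sorted(self):
        paths = [
            CascadePath(("a", "b"), raw=1.4, normalized=0.70),
            CascadePath(("c", "d"), raw=1.8, normalized=0.90),
            CascadePath(("e", "f"), raw=1.6, normalized=0.80),
        ]
        kept = retain_cascades(paths, 0.7)
        assert [p.normalized for p in kept] == [0.90, 0.80]
        assert all(p.retained for p in kept)

    def test_empty_input(self):
        assert retain_cascades([], 0.7) == []

    def test_raw_variant(self):
        paths = [CascadePath(("a", "b"), raw=5.0, normalized=2.5)]
        assert retain_cascades(paths, 4.0, score="raw") == paths
        assert retain_cascades(paths, 6.0, score="raw") == []


class TestMergeModules:
    def test_disjoint_chains_two_modules(self):
        paths = [
            CascadePath(("a", "b", "c"), 1, 1),
            CascadePath(("x", "y", "z"), 1, 1),
        ]
        assert len(merge_modules(paths)) == 2

    def test_edge_sharing_merges(self):
        paths = [
            CascadePath(("a", "b", "c"), 1, 1),
            CascadePath(("a", "b", "d"), 1, 1),  # shares edge a->b
        ]
        mods = merge_modules(paths)
        assert len(mods) == 1 and sorted(mods[0].nodes) == ["a", "b", "c", "d"]

    def test_node_only_sharing_kept_separate_by_default(self):
        paths = [
            CascadePath(("a", "b", "f"), 1, 1),
            CascadePath(("x", "y", "f"), 1, 1),  # shares only node f
        ]
        assert len(merge_modules(paths, by="edge")) == 2
        assert len(merge_modules(paths, by="node")) == 1

    def test_roles_attached_from_graph(self):
        g = chain_graph("ab", in_tg=True, in_pg=False, nv=0, nc=1, im=0.0)
        g.nodes["b"]["in_pg"] = True
        (mod,) = merge_modules([CascadePath(("a", "b"), 1, 1)], graph=g)
        assert mod.nodes["a"]["role"] == "target-only"
        assert mod.nodes["b"]["role"] == "both"

    def test_no_retained_is_error(self):
        with pytest.raises(ValueError):
            merge_modules([])


class TestAnnotate:
    def test_attributes_complete_and_im_from_undirected_view(self):
        g = nx.DiGraph([("r", "m"), ("m", "t")])
        ann = annotate_signaling_graph(g, tg={"m"}, pg_nv={"t": 4}, nc={"m": 2})
        assert ann.nodes["m"]["in_tg"] and not ann.nodes["m"]["in_pg"]
        assert ann.nodes["t"]["nv"] == 4
        assert ann.nodes["m"]["im"] > 0  # transit node of the 3-chain
        assert ann.nodes["r"]["im"] == 0
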