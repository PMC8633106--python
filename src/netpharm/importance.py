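"""Node importance (IM), baseline centralities, and the effective intervention space.

The importance score of node *i* combines how short the shortest paths
transiting *i* are with how many of the network's shortest paths *i*
carries::

    IM_i = ((D + 1) - L_i) / D  *  B_i / (n (n - 1) / 2)

where ``D`` is the effective diameter (the largest finite hop distance,
taken across connected components when the graph is disconnected),
``L_i`` is the mean length of shortest paths passing through *i* (each
geodesic counted once, endpoints excluded), ``B_i`` is the transit
betweenness sum over unordered pairs {j, k} with j != i != k of
g_jk(i) / g_jk (fraction of the pair's geodesics through *i*), and *n*
is the node count.  A node no geodesic transits has IM = 0.  The pair
normalization n(n-1)/2 — rather than the (n-1)(n-2)/2 of classical
betweenness — keeps the second factor strictly below 1.

The effective intervention space (EIS) is the induced subgraph on nodes
whose IM strictly exceeds the network median IM; its members are the
intervention-response proteins, each categorized as essential-common
(target and pathogenic), disease-specific (pathogenic only) or
component-specific (target only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ImportanceTable",
    "EffectiveInterventionSpace",
    "effective_diameter",
    "node_importance",
    "baseline_centralities",
    "extract_eis",
    "categorize_nodes",
    "BASELINE_METHODS",
]

log = logging.getLogger(__name__)

BASELINE_METHODS = (
    "degree",
    "betweenness",
    "closeness",
    "clustering",
    "neighborhood_connectivity",
)


@dataclass
class ImportanceTable:
    """Per-node IM (and baseline) scores for one graph."""

    graph_id: str
    eff_diameter: int
    scores: pd.DataFrame  # index: node; columns: im + baselines

    @property
    def im_median(self) -> float:
        return float(np.median(self.scores["im"].to_numpy()))

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "node"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# graph_id={self.graph_id}\teff_diameter={self.eff_diameter}\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ImportanceTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().lstrip("# ").rstrip("\n").split("\t")
            meta = dict(kv.split("=", 1) for kv in header)
            scores = pd.read_csv(fh, sep="\t", index_col="node")
        return cls(
            graph_id=meta["graph_id"],
            eff_diameter=int(meta["eff_diameter"]),
            scores=scores,
        )


def _distances_and_path_counts(
    graph: nx.Graph, nodes: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and geodesic counts via per-source BFS."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    for s in nodes:
        si = index[s]
        dist[si, si] = 0.0
        sigma[si, si] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt: list = []
            for v in frontier:
                vi = index[v]
                for w in adj[v]:
                    wi = index[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = d + 1
                        nxt.append(w)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, vi]
            frontier = nxt
            d += 1
    return dist, sigma


def effective_diameter(graph: nx.Graph) -> int:
    """Largest finite hop distance; max across components if disconnected."""
    if graph.number_of_nodes() < 2:
        raise ValueError("diameter undefined: graph has fewer than 2 nodes")
    best = 0
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue  # isolated nodes contribute 0
        sub = graph.subgraph(comp)
        ecc = nx.eccentricity(sub)
        best = max(best, max(ecc.values()))
    return int(best)


def node_importance(
    graph: nx.Graph, graph_id: str = "graph", with_baselines: bool = True
) -> ImportanceTable:
    """Compute IM (and optionally baseline centralities) for every node.

    Requires a simple undirected graph with >= 3 nodes and at least one
    edge.  Pairs split across components contribute nothing (their
    geodesic count is zero).
    """
    if graph.number_of_nodes() < 3:
        raise ValueError("node_importance requires >= 3 nodes")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    eff_d = effective_diameter(graph)
    if eff_d == 0:
        raise ValueError("all nodes isolated: importance undefined")

    dist, sigma = _distances_and_path_counts(graph, nodes)
    finite = np.isfinite(dist)
    pair_norm = n * (n - 1) / 2.0

    im = np.zeros(n)
    with np.errstate(invalid="ignore"):
        frac_base = np.where(sigma > 0, 1.0 / np.where(sigma > 0, sigma, 1.0), 0.0)
    for i in range(n):
        # pair {j,k} transits i iff d(j,i) + d(i,k) == d(j,k), j != i != k
        through = (dist[:, i][:, None] + dist[i, :][None, :] == dist) & finite
        through[i, :] = False
        through[:, i] = False
        np.fill_diagonal(through, False)
        if not through.any():
            continue
        g_i = sigma[:, i][:, None] * sigma[i, :][None, :]  # geodesics via i
        m_i = g_i[through].sum() / 2.0  # unordered pairs
        if m_i == 0:
            continue
        sum_len = (g_i * np.where(through, dist, 0.0))[through].sum() / 2.0
        transit_bt = (g_i * frac_base)[through].sum() / 2.0
        first = ((eff_d + 1) - sum_len / m_i) / eff_d
        im[i] = first * transit_bt / pair_norm

    scores = pd.DataFrame({"im": im}, index=pd.Index(nodes, name="node"))
    if with_baselines:
        scores = scores.join(baseline_centralities(graph))
    log.info(
        "importance on %s: n=%d, eff_diameter=%d, median IM=%.3g",
        graph_id,
        n,
        eff_d,
        float(np.median(im)),
    )
    return ImportanceTable(graph_id=graph_id, eff_diameter=eff_d, scores=scores)


def baseline_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Standard per-node centralities used as comparison baselines.

    degree, betweenness (endpoint-excluding, normalized over transit
    pairs), closeness, clustering coefficient, and neighborhood
    connectivity (mean degree of neighbors; 0 for isolated nodes).
    """
    nodes = sorted(graph.nodes)
    deg = dict(graph.degree())
    bet = nx.betweenness_centrality(graph, normalized=True, endpoints=False)
    clo = nx.closeness_centrality(graph)
    clu = nx.clustering(graph)
    nbc = {
        v: (sum(deg[w] for w in graph.neighbors(v)) / deg[v]) if deg[v] else 0.0
        for v in nodes
    }
    return pd.DataFrame(
        {
            "degree": [float(deg[v]) for v in nodes],
            "betweenness": [bet[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "clustering": [clu[v] for v in nodes],
            "neighborhood_connectivity": [nbc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


CATEGORIES = ("essential_common", "disease_specific", "component_specific")


@dataclass
class EffectiveInterventionSpace:
    """Induced subgraph of the T-P network on above-median-IM nodes."""

    graph: nx.Graph
    im_median: float
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for c in self.categories.values():
            out[c] += 1
        return out

    def to_json_dict(self) -> dict:
        return {
            "im_median": self.im_median,
            "nodes": self.nodes,
            "edges": sorted([sorted(e) for e in self.graph.edges]),
            "categories": dict(sorted(self.categories.items())),
        }


def extract_eis(
    tp_graph: nx.Graph,
    importance: ImportanceTable,
    mode: Literal["strict", "ge"] = "strict",
) -> EffectiveInterventionSpace:
    """Keep nodes whose IM exceeds the median IM; induce their subgraph.

    ``mode="strict"`` (default) keeps im > median — ties at the median
    are excluded, deterministically.  ``mode="ge"`` keeps im >= median.
    """
    im = importance.scores["im"]
    missing = set(tp_graph.nodes) - set(im.index)
    if missing:
        raise ValueError(f"importance table lacks scores for {sorted(missing)[:5]}...")
    med = importance.im_median
    if mode == "strict":
        kept = [v for v in tp_graph.nodes if im[v] > med]
    else:
        kept = [v for v in tp_graph.nodes if im[v] >= med]
    if not kept:
        raise ValueError(
            "empty effective intervention space (all scores tie at the median); "
            "consider mode='ge'"
        )
    sub = tp_graph.subgraph(kept).copy()
    log.info(
        "EIS: kept %d of %d nodes (median IM %.3g), %d edges",
        len(kept),
        tp_graph.number_of_nodes(),
        med,
        sub.number_of_edges(),
    )
    return EffectiveInterventionSpace(graph=sub, im_median=med)


def categorize_nodes(
    eis: EffectiveInterventionSpace,
    target_set: Iterable[str],
    pathogenic_set: Iterable[str],
) -> dict[str, str]:
    """Partition EIS nodes into the three intervention-response categories."""
    targets = set(target_set)
    pathogenic = set(pathogenic_set)
    cats: dict[str, str] = {}
    for v in eis.nodes:
        in_t, in_p = v in targets, v in pathogenic
        if in_t and in_p:
            cats[v] = "essential_common"
        elif in_p:
            cats[v] = "disease_specific"
        elif in_t:
            cats[v] = "component_specific"
        else:
            raise ValueError(f"node {v!r} is neither target nor pathogenic")
    eis.categories = cats
    return cats
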