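"""Maximum-targeting-weight (MTW) scoring of signaling cascades.

A directed signaling graph carries per-node annotations: membership in
the target-gene set TG and the pathogenic-gene set PG, the literature
evidence count NV, the regulating-component count NC, and the topological
importance IM.  Evidence and regulation are min–max scaled over the PG
and TG node sets respectively::

    R_i = (NV_i - min NV over PG) / (max - min)      clipped to [0, 1]
    D_i = (NC_i - min NC over TG) / (max - min)      clipped to [0, 1]

A cascade is a minimum-weight directed path from a receptor (source) to
an effector (sink); Dijkstra finds one per reachable pair, with ties
broken toward the lexicographically smallest node sequence.  Each node
on a cascade contributes ``IM_i + R_i + D_i`` plus membership
corrections ``±R_avg ±D_avg`` (+R_avg when the node is pathogenic, else
-R_avg; +D_avg when it is a target, else -D_avg), where R_avg and D_avg
are the mean R over PG and mean D over TG.  The raw score is the sum
over path nodes; because the sum grows with path length, the default
reported score is the per-node mean, and retention (score > 0.7 by
default) applies to that normalized score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx

__all__ = [
    "ScoreContext",
    "CascadePath",
    "normalize_evidence",
    "normalize_regulation",
    "shortest_cascades",
    "score_cascade",
    "retain_cascades",
    "merge_modules",
    "annotate_signaling_graph",
]

log = logging.getLogger(__name__)

NODE_ATTRS = ("in_tg", "in_pg", "nv", "nc", "im")


def normalize_evidence(nv: float, pg_bounds: tuple[float, float]) -> float:
    """Min–max scale an evidence count against the PG bounds; degenerate -> 0."""
    if nv < 0:
        raise ValueError(f"nv must be >= 0, got {nv}")
    lo, hi = pg_bounds
    if hi == lo:
        return 0.0
    return min(1.0, max(0.0, (nv - lo) / (hi - lo)))


def normalize_regulation(nc: float, tg_bounds: tuple[float, float]) -> float:
    """Min–max scale a regulating-component count against the TG bounds."""
    if nc < 0:
        raise ValueError(f"nc must be >= 0, got {nc}")
    lo, hi = tg_bounds
    if hi == lo:
        return 0.0
    return min(1.0, max(0.0, (nc - lo) / (hi - lo)))


@dataclass(frozen=True)
class ScoreContext:
    """Normalization bounds plus the PG/TG mean strengths R_avg and D_avg."""

    r_avg: float
    d_avg: float
    pg_bounds: tuple[float, float]
    tg_bounds: tuple[float, float]

    @classmethod
    def from_graph(cls, graph: nx.DiGraph) -> "ScoreContext":
        pg = [n for n, d in graph.nodes(data=True) if d.get("in_pg")]
        tg = [n for n, d in graph.nodes(data=True) if d.get("in_tg")]
        if not pg or not tg:
            raise ValueError("graph must contain at least one PG node and one TG node")
        nvs = [graph.nodes[n]["nv"] for n in pg]
        ncs = [graph.nodes[n]["nc"] for n in tg]
        pg_bounds = (min(nvs), max(nvs))
        tg_bounds = (min(ncs), max(ncs))
        r_avg = sum(normalize_evidence(v, pg_bounds) for v in nvs) / len(nvs)
        d_avg = sum(normalize_regulation(c, tg_bounds) for c in ncs) / len(ncs)
        return cls(r_avg=r_avg, d_avg=d_avg, pg_bounds=pg_bounds, tg_bounds=tg_bounds)


@dataclass
class CascadePath:
    """An ordered receptor-to-effector chain with its MTW scores."""

    nodes: tuple[str, ...]
    raw: float
    normalized: float
    retained: bool = False

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a cascade needs at least 2 nodes")

    def label(self) -> str:
        return "--".join(self.nodes)


def shortest_cascades(
    graph: nx.DiGraph,
    sources: Iterable[str] | None = None,
    sinks: Iterable[str] | None = None,
    weight: str = "weight",
) -> list[tuple[str, ...]]:
    """One minimum-weight directed path per reachable (source, sink) pair.

    Sources default to in-degree-0 nodes (extracellular receptors),
    sinks to out-degree-0 nodes (terminal effectors).  Among
    minimum-weight paths for a pair, the lexicographically smallest node
    sequence is returned; unreachable pairs are omitted and logged.
    """
    if sources is None:
        sources = [n for n in graph if graph.in_degree(n) == 0]
    if sinks is None:
        sinks = [n for n in graph if graph.out_degree(n) == 0]
    sources, sinks = sorted(set(sources)), sorted(set(sinks))
    if not sources or not sinks:
        raise ValueError("need non-empty source and sink sets")
    paths: list[tuple[str, ...]] = []
    skipped = 0
    for s in sources:
        for t in sinks:
            if s == t:
                continue
            try:
                best = min(
                    nx.all_shortest_paths(graph, s, t, weight=weight, method="dijkstra")
                )
            except nx.NetworkXNoPath:
                skipped += 1
                continue
            paths.append(tuple(best))
    if skipped:
        log.info("shortest_cascades: %d source-sink pairs unreachable", skipped)
    return paths


def _node_term(graph: nx.DiGraph, node: str, ctx: ScoreContext) -> float:
    data = graph.nodes[node]
    for attr in NODE_ATTRS:
        if attr not in data:
            raise ValueError(f"node {node!r} missing attribute {attr!r}")
    r = normalize_evidence(data["nv"], ctx.pg_bounds)
    d = normalize_regulation(data["nc"], ctx.tg_bounds)
    term = data["im"] + r + d
    term += ctx.r_avg if data["in_pg"] else -ctx.r_avg
    term += ctx.d_avg if data["in_tg"] else -ctx.d_avg
    return term


def score_cascade(
    path: Sequence[str], graph: nx.DiGraph, context: ScoreContext
) -> CascadePath:
    """Sum the per-node MTW terms along a path; also report the per-node mean."""
    raw = sum(_node_term(graph, v, context) for v in path)
    return CascadePath(nodes=tuple(path), raw=raw, normalized=raw / len(path))


def retain_cascades(
    paths: Sequence[CascadePath],
    threshold: float = 0.7,
    score: Literal["normalized", "raw"] = "normalized",
) -> list[CascadePath]:
    """Keep cascades whose score strictly exceeds the threshold.

    Returns the retained cascades in descending score order (stable for
    ties) with their ``retained`` flags set.
    """
    key = (lambda p: p.normalized) if score == "normalized" else (lambda p: p.raw)
    kept = [p for p in paths if key(p) > threshold]
    kept.sort(key=lambda p: -key(p))
    for p in kept:
        p.retained = True
    return kept


def merge_modules(
    retained: Sequence[CascadePath],
    graph: nx.DiGraph | None = None,
    by: Literal["edge", "node"] = "edge",
) -> list[nx.DiGraph]:
    """Merge retained cascades into cascade-targeting modules.

    Cascades are grouped transitively by shared directed edges (default)
    or shared nodes; each group's union of path edges is one module.
    Edge sharing is the default because distinct mechanism modules may
    converge on a common downstream effector without sharing any
    signaling step.  Node role labels (``both`` / ``target-only`` /
    ``pathogenic-only`` / ``other``) are attached from the signaling
    graph's TG/PG annotations when a graph is given.
    """
    if not retained:
        raise ValueError("no retained cascades to merge")
    edge_sets = [set(zip(p.nodes, p.nodes[1:])) for p in retained]
    node_sets = [set(p.nodes) for p in retained]
    link = nx.Graph()
    link.add_nodes_from(range(len(retained)))
    items = edge_sets if by == "edge" else node_sets
    for i in range(len(retained)):
        for j in range(i + 1, len(retained)):
            if items[i] & items[j]:
                link.add_edge(i, j)
    modules: list[nx.DiGraph] = []
    for group in sorted(nx.connected_components(link), key=lambda g: sorted(g)[0]):
        mod = nx.DiGraph()
        for idx in sorted(group):
            mod.add_edges_from(edge_sets[idx])
        for v in mod.nodes:
            if graph is not None and v in graph:
                in_tg = bool(graph.nodes[v].get("in_tg"))
                in_pg = bool(graph.nodes[v].get("in_pg"))
                mod.nodes[v]["role"] = (
                    "both"
                    if in_tg and in_pg
                    else "target-only"
                    if in_tg
                    else "pathogenic-only"
                    if in_pg
                    else "other"
                )
            else:
                mod.nodes[v]["role"] = "other"
        modules.append(mod)
    return modules


def annotate_signaling_graph(
    graph: nx.DiGraph,
    tg: Iterable[str],
    pg_nv: dict[str, int],
    nc: dict[str, int],
    im: dict[str, float] | None = None,
) -> nx.DiGraph:
    """Attach TG/PG membership, NV, NC and IM attributes to every node.

    IM defaults to importance computed on the undirected view of the
    signaling graph itself.
    """
    from .importance import node_importance

    g = graph.copy()
    tg = set(tg)
    if im is None:
        und = nx.Graph(g.to_undirected())
        im_table = node_importance(und, graph_id="signaling", with_baselines=False)
        im = im_table.scores["im"].to_dict()
    for v in g.nodes:
        g.nodes[v]["in_tg"] = v in tg
        g.nodes[v]["in_pg"] = v in pg_nv
        g.nodes[v]["nv"] = pg_nv.get(v, 0)
        g.nodes[v]["nc"] = nc.get(v, 0)
        g.nodes[v]["im"] = float(im.get(v, 0.0))
    return g
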