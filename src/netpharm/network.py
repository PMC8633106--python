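"""Assembly of the component–target–pathogenic-gene–disease (CTPD) network.

The CTPD graph is a simple undirected graph with typed layers:

* ``CT`` edges connect components to their predicted target genes;
* ``PPI`` edges connect gene nodes (targets and/or pathogenic genes);
* ``GD`` edges connect each pathogenic gene to the single disease node.

Node roles are sets drawn from {component, target, pathogenic, disease};
a gene may be both target and pathogenic.  Each target node carries
``nc``, the number of components that regulate it (its count of CT
edges); each pathogenic node carries ``nv``, its literature-evidence
count.  Where layers would create a parallel edge the strongest type
wins with precedence CT > GD > PPI, keeping the graph simple.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .io import ComponentRecord, GeneSetCollection, PathogenicGene

__all__ = [
    "build_ct_network",
    "assemble_ctpd",
    "extract_tp",
    "bin_evidence_profile",
    "component_nodes",
    "gene_nodes",
]

log = logging.getLogger(__name__)

_TYPE_RANK = {"CT": 3, "GD": 2, "PPI": 1}


def _add_role(g: nx.Graph, node: str, role: str) -> None:
    if node not in g:
        g.add_node(node, roles=set())
    g.nodes[node].setdefault("roles", set()).add(role)


def _add_typed_edge(g: nx.Graph, u: str, v: str, etype: str) -> None:
    # parallel layers collapse to one edge; strongest type wins
    if g.has_edge(u, v):
        if _TYPE_RANK[etype] > _TYPE_RANK[g.edges[u, v]["etype"]]:
            g.edges[u, v]["etype"] = etype
    else:
        g.add_edge(u, v, etype=etype)


def component_nodes(g: nx.Graph) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if "component" in d["roles"])


def gene_nodes(g: nx.Graph) -> list[str]:
    return sorted(
        n for n, d in g.nodes(data=True) if d["roles"] & {"target", "pathogenic"}
    )


def build_ct_network(
    components: Sequence[ComponentRecord], ct_edges: pd.DataFrame
) -> nx.Graph:
    """Build the bipartite component–target layer.

    ``ct_edges`` needs ``source`` (component id) and ``target`` (gene
    symbol) columns.  Every edge's component must exist in ``components``;
    unknown components are a hard error listing the offenders.  Target
    nodes receive ``nc`` = number of distinct components hitting them.
    """
    g = nx.Graph()
    known = {c.component_id for c in components}
    for c in components:
        _add_role(g, c.component_id, "component")
    offenders = sorted(set(ct_edges["source"]) - known)
    if offenders:
        raise ValueError(f"CT edges reference unknown component(s): {offenders}")
    for row in ct_edges.itertuples(index=False):
        _add_role(g, row.target, "target")
        _add_typed_edge(g, row.source, row.target, "CT")
    for n, d in g.nodes(data=True):
        if "target" in d["roles"]:
            d["nc"] = sum(
                1 for nb in g.neighbors(n) if "component" in g.nodes[nb]["roles"]
            )
    n_comp = len(known)
    n_edges = sum(1 for *_, d in g.edges(data=True) if d["etype"] == "CT")
    log.info(
        "C-T layer: %d components, %d targets, %d edges (mean targets/component %.2f)",
        n_comp,
        g.number_of_nodes() - n_comp,
        n_edges,
        n_edges / n_comp if n_comp else 0.0,
    )
    return g


def assemble_ctpd(
    ct_net: nx.Graph,
    ppi_edges: pd.DataFrame,
    pathogenic_genes: Sequence[PathogenicGene],
    disease_label: str = "disease",
    expand_ppi: bool = False,
) -> nx.Graph:
    """Overlay PPI edges and pathogenic genes onto the C-T layer.

    Pathogenic genes are added with their ``nv`` and linked to the single
    disease node by GD edges.  PPI edges are kept only when both
    endpoints are already gene nodes (target or pathogenic); with
    ``expand_ppi`` an edge with exactly one known endpoint pulls in its
    neighbor as a plain target-less gene node.  Unmatched rows are
    counted and logged, never fatal.
    """
    g = ct_net.copy()
    for p in pathogenic_genes:
        _add_role(g, p.symbol, "pathogenic")
        g.nodes[p.symbol]["nv"] = p.nv

    def is_gene(n: str) -> bool:
        return n in g and bool(g.nodes[n]["roles"] & {"target", "pathogenic"})

    unmatched = 0
    for row in ppi_edges.itertuples(index=False):
        u, v = row.source, row.target
        if u == v:
            continue
        ku, kv = is_gene(u), is_gene(v)
        if ku and kv:
            _add_typed_edge(g, u, v, "PPI")
        elif expand_ppi and (ku or kv):
            new = v if ku else u
            _add_role(g, new, "target")
            g.nodes[new].setdefault("nc", 0)
            _add_typed_edge(g, u, v, "PPI")
        else:
            unmatched += 1
    if unmatched:
        log.info("assemble_ctpd: %d PPI rows had no matching gene endpoint", unmatched)

    _add_role(g, disease_label, "disease")
    for p in pathogenic_genes:
        _add_typed_edge(g, p.symbol, disease_label, "GD")
    g.graph["disease"] = disease_label
    log.info(
        "CTPD network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges()
    )
    return g


def extract_tp(ctpd: nx.Graph) -> nx.Graph:
    """Induce the target–pathogenic-gene (T-P) subnetwork with PPI edges only.

    Keeps every node whose role set intersects {target, pathogenic}
    (with nv/nc attributes) and only the PPI edges among them.  Isolated
    genes remain as isolated nodes.
    """
    genes = gene_nodes(ctpd)
    if not genes:
        raise ValueError("no gene layer: CTPD network has no target or pathogenic nodes")
    tp = nx.Graph()
    for n in genes:
        tp.add_node(n, **{k: v for k, v in ctpd.nodes[n].items()})
        tp.nodes[n]["roles"] = set(ctpd.nodes[n]["roles"]) & {"target", "pathogenic"}
    for u, v, d in ctpd.edges(data=True):
        if d["etype"] == "PPI" and u in tp and v in tp:
            tp.add_edge(u, v, etype="PPI")
    return tp


def bin_evidence_profile(
    pathogenic_genes: Sequence[PathogenicGene],
    term_collection: GeneSetCollection,
    bins: Iterable[tuple[float, float]],
) -> pd.DataFrame:
    """Profile evidence counts against functional annotation breadth.

    ``bins`` are disjoint half-open intervals [lo, hi) that must cover
    [1, inf).  For each bin: the number of genes whose nv falls inside,
    and the mean number of collection terms containing each such gene
    (genes in no term count as 0 terms).
    """
    bins = sorted((float(lo), float(hi)) for lo, hi in bins)
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping bins: [{lo1},{hi1}) and [{lo2},...)")
        if hi1 < lo2:
            raise ValueError(f"gap between bins at {hi1}..{lo2}")
    if not bins or bins[0][0] > 1 or bins[-1][1] != float("inf"):
        raise ValueError("bins must cover [1, inf)")
    term_counts = term_collection.terms_per_gene()
    rows = []
    for lo, hi in bins:
        members = [g for g in pathogenic_genes if lo <= g.nv < hi]
        mean_terms = (
            sum(term_counts.get(g.symbol, 0) for g in members) / len(members)
            if members
            else 0.0
        )
        rows.append(
            {"bin_lo": lo, "bin_hi": hi, "n_genes": len(members), "mean_terms": mean_terms}
        )
    return pd.DataFrame(rows)
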