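"""Seeded generator of a full toy formula→disease bundle.

Every pipeline stage can be exercised offline on data this module
emits: a component property table with controlled ADME-rule violations,
herb membership, component→target edges, a scale-free protein–protein
interaction layer, heavy-tailed literature-evidence counts, overlapping
gene sets tied to network modules, and a layered directed signaling
graph.  The generator is constructive rather than statistical where the
downstream assertion is exact: it *plants* ground truths — a hub set
that the effective intervention space must recover, a minimal component
cover that greedy selection must return, and a maximally attributed
signaling chain that cascade scoring must rank first — and records them
in a ledger next to the emitted files.

The PPI layer grows by preferential attachment from a ring of designated
hub genes, each anchored by dedicated leaf genes.  Hubs are therefore
cut vertices carrying transit shortest paths (importance > 0) while the
majority of genes are leaves (importance exactly 0), so the median
importance is 0 and the hub set lies inside the EIS by construction.

Planted-cover construction: the generator computes the EIS itself, splits
the coverable EIS targets into strictly decreasing chunks — one per
planted component — and caps every decoy component's EIS-target count
below the smallest chunk, so best-first selection provably picks the
planted components, in order, before any decoy.

One master seed fans out to per-section seeds (SeedSequence spawning),
so adding a generator section never perturbs earlier sections, and
regenerating with the same seed and parameters is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .importance import extract_eis, node_importance
from .io import (
    ComponentRecord,
    GeneSetCollection,
    PathogenicGene,
    dump_json,
    write_component_table,
    write_edges,
    write_gmt,
    write_pathogenic_table,
)
from .mtw import annotate_signaling_graph

__all__ = ["SyntheticParams", "SyntheticBundle", "generate", "generate_signaling"]

log = logging.getLogger(__name__)

_HERBS = ("CH", "CP", "CX", "XF", "ZQ", "SY", "GC")


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the toy bundle; defaults keep the full pipeline in seconds."""

    n_herbs: int = 7
    n_components: int = 200
    n_genes: int = 300
    n_hubs: int = 10
    n_pathogenic: int = 160
    n_pathogenic_only: int = 50  # pathogenic genes no component targets
    n_planted_cover: int = 7
    adme_violation_rate: float = 0.3  # fraction of decoy components failing one rule
    p_extra_edge: float = 0.05  # chance a new gene gets a second PPI edge
    nv_zipf_a: float = 2.2
    nv_max: int = 50
    n_random_terms: int = 15
    # signaling section
    chain_len: int = 5
    n_layers: int = 4
    layer_width: int = 6
    p_forward: float = 0.35

    def __post_init__(self) -> None:
        if self.n_planted_cover > self.n_components:
            raise ValueError("planted cover size exceeds component count")
        if self.n_pathogenic_only >= self.n_pathogenic:
            raise ValueError("n_pathogenic_only must be < n_pathogenic")
        if self.n_pathogenic > self.n_genes:
            raise ValueError("more pathogenic genes than genes")
        if self.n_hubs * 3 + 2 > self.n_genes:
            raise ValueError("too few genes for the requested hub scaffold")
        if self.chain_len < 3:
            raise ValueError("chain_len must be >= 3")
        if not 0 <= self.adme_violation_rate <= 1:
            raise ValueError("adme_violation_rate must be in [0, 1]")


@dataclass
class SyntheticBundle:
    """In-memory bundle plus the ledger of planted ground truths."""

    params: SyntheticParams
    seed: int
    components: list[ComponentRecord]
    ct_edges: pd.DataFrame
    ppi_edges: pd.DataFrame
    pathogenic: list[PathogenicGene]
    collection: GeneSetCollection
    signaling: nx.DiGraph
    ledger: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_component_table(out / "components.tsv", self.components)
        write_edges(out / "ct_edges.tsv", self.ct_edges)
        write_edges(out / "ppi_edges.tsv", self.ppi_edges)
        write_pathogenic_table(out / "pathogenic.tsv", self.pathogenic)
        write_gmt(out / "genesets.gmt", self.collection)
        sig_edges = pd.DataFrame(
            [{"source": u, "target": v} for u, v in sorted(self.signaling.edges)]
        )
        write_edges(out / "signaling_edges.tsv", sig_edges)
        rows = []
        for v in sorted(self.signaling.nodes):
            d = self.signaling.nodes[v]
            rows.append(
                {
                    "node": v,
                    "in_tg": int(d["in_tg"]),
                    "in_pg": int(d["in_pg"]),
                    "nv": d["nv"],
                    "nc": d["nc"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "signaling_nodes.tsv", sep="\t", index=False)
        dump_json(out / "ledger.json", self.ledger)


# ---------------------------------------------------------------------------


def _gene(i: int) -> str:
    return f"G{i:04d}"


def _comp(i: int) -> str:
    return f"C{i:03d}"


def _build_ppi(params: SyntheticParams, rng: np.random.Generator) -> tuple[nx.Graph, list[str]]:
    """Hub-anchored preferential-attachment graph; returns (graph, hubs)."""
    hubs = [_gene(i) for i in range(params.n_hubs)]
    g = nx.Graph()
    g.add_nodes_from(hubs)
    for i in range(params.n_hubs):  # hub ring backbone
        g.add_edge(hubs[i], hubs[(i + 1) % params.n_hubs])
    next_gene = params.n_hubs
    for h in hubs:  # two dedicated leaves anchor each hub as a cut vertex
        for _ in range(2):
            g.add_edge(h, _gene(next_gene))
            next_gene += 1
    while next_gene < params.n_genes:
        new = _gene(next_gene)
        nodes = sorted(g.nodes)
        deg = np.array([g.degree(v) for v in nodes], dtype=float)
        anchor = rng.choice(nodes, p=deg / deg.sum())
        g.add_edge(new, anchor)
        if rng.random() < params.p_extra_edge:
            other = rng.choice(nodes, p=deg / deg.sum())
            if other != new and other != anchor:
                g.add_edge(new, other)
        next_gene += 1
    return g, hubs


def _split_cover(q: int, k: int) -> list[int]:
    """Strictly decreasing positive chunk sizes summing to q."""
    base = q // k
    half = k // 2
    sizes = [base + (half - i) for i in range(k)]
    sizes[0] += q - sum(sizes)
    if sizes[-1] < 1 or any(a <= b for a, b in zip(sizes, sizes[1:])):
        raise ValueError(
            f"cannot split {q} coverable EIS targets into {k} strictly "
            "decreasing chunks; lower n_planted_cover or raise n_genes"
        )
    return sizes


def _component_properties(
    comp_id: str,
    name: str,
    herbs: frozenset[str],
    violate: str | None,
    rng: np.random.Generator,
) -> ComponentRecord:
    """A record passing every default rule, or violating exactly one."""
    props = dict(
        mw=round(float(rng.uniform(120, 480)), 2),
        hdon=int(rng.integers(0, 5)),
        hacc=int(rng.integers(0, 9)),
        rbn=int(rng.integers(0, 9)),
        logp=round(float(rng.uniform(-1.5, 4.5)), 2),
        ob=round(float(rng.uniform(32, 95)), 2),
        gi_class="high",
        herg_class=str(rng.choice(["low", "medium"])),
        carcinogenicity="negative",
    )
    if violate == "mw":
        props["mw"] = round(float(rng.uniform(520, 900)), 2)
    elif violate == "hdon":
        props["hdon"] = int(rng.integers(6, 11))
    elif violate == "hacc":
        props["hacc"] = int(rng.integers(11, 16))
    elif violate == "rbn":
        props["rbn"] = int(rng.integers(11, 21))
    elif violate == "logp":
        props["logp"] = round(float(rng.uniform(5.5, 9.0)), 2)
    elif violate == "ob":
        props["ob"] = round(float(rng.uniform(2, 28)), 2)
    elif violate == "gi":
        props["gi_class"] = "low"
    elif violate == "herg":
        props["herg_class"] = "high"
    elif violate == "carcinogenicity":
        props["carcinogenicity"] = "positive"
    return ComponentRecord(component_id=comp_id, name=name, herbs=herbs, **props)


_VIOLATIONS = ("mw", "hdon", "hacc", "rbn", "logp", "ob", "gi", "herg", "carcinogenicity")


def generate(
    params: SyntheticParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticBundle:
    """Generate the full bundle; write it (plus ledger.json) if out_dir given."""
    params = params or SyntheticParams()
    ss = np.random.SeedSequence(seed)
    rng_ppi, rng_pg, rng_adme, rng_ct, rng_gmt, rng_sig = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    # --- PPI layer with planted hubs ---------------------------------------
    ppi, hubs = _build_ppi(params, rng_ppi)
    genes = sorted(ppi.nodes)

    # --- pathogenic genes with heavy-tailed evidence ------------------------
    non_hub = [g for g in genes if g not in hubs]
    chosen = list(rng_pg.choice(non_hub, size=params.n_pathogenic - len(hubs) // 2, replace=False))
    pathogenic_syms = sorted(set(hubs[: len(hubs) // 2]) | set(chosen))
    nv = np.minimum(rng_pg.zipf(params.nv_zipf_a, size=len(pathogenic_syms)), params.nv_max)
    pathogenic = [PathogenicGene(symbol=s, nv=int(v)) for s, v in zip(pathogenic_syms, nv)]
    pathogenic_only = set(
        rng_pg.choice(
            [s for s in pathogenic_syms if s not in hubs],
            size=params.n_pathogenic_only,
            replace=False,
        )
    )
    target_genes = sorted(set(genes) - pathogenic_only)

    # --- compute the EIS the way the pipeline will --------------------------
    tp = nx.Graph()
    for v in genes:
        roles = set()
        if v in target_genes:
            roles.add("target")
        if v in pathogenic_only or v in pathogenic_syms:
            roles.add("pathogenic")
        tp.add_node(v, roles=roles)
    tp.add_edges_from(ppi.edges, etype="PPI")
    table = node_importance(tp, graph_id="synthetic-tp", with_baselines=False)
    eis = extract_eis(tp, table)
    eis_nodes = sorted(eis.graph.nodes)
    coverable = sorted(set(eis_nodes) & set(target_genes))

    # --- plant the minimal cover -------------------------------------------
    k = params.n_planted_cover
    sizes = _split_cover(len(coverable), k)
    decoy_cap = max(0, sizes[-1] - 1)
    shuffled = list(coverable)
    rng_ct.shuffle(shuffled)
    chunks, pos = [], 0
    for s in sizes:
        chunks.append(shuffled[pos : pos + s])
        pos += s
    planted_ids = [_comp(i) for i in range(k)]

    # --- ADME fates ---------------------------------------------------------
    comp_ids = [_comp(i) for i in range(params.n_components)]
    violations: dict[str, str] = {}
    for cid in comp_ids[k:]:
        if rng_adme.random() < params.adme_violation_rate:
            violations[cid] = str(rng_adme.choice(_VIOLATIONS))
    herbs_avail = _HERBS[: params.n_herbs]
    components = []
    for cid in comp_ids:
        n_h = 1 + int(rng_adme.random() < 0.15) + int(rng_adme.random() < 0.05)
        herbs = frozenset(rng_adme.choice(herbs_avail, size=min(n_h, len(herbs_avail)), replace=False))
        components.append(
            _component_properties(cid, f"cmpd-{cid}", herbs, violations.get(cid), rng_adme)
        )
    passing = [c.component_id for c in components if c.component_id not in violations]

    # --- C-T edges: planted chunks + preferential decoys --------------------
    ct_rows: list[tuple[str, str]] = []
    for cid, chunk in zip(planted_ids, chunks):
        for t in chunk:
            ct_rows.append((cid, t))
        extras = rng_ct.choice(
            [t for t in target_genes if t not in eis_nodes],
            size=int(rng_ct.integers(1, 4)),
            replace=False,
        )
        ct_rows.extend((cid, t) for t in extras)
    non_eis_pool = [t for t in target_genes if t not in eis_nodes]
    ct_degree = {t: 1 for t in non_eis_pool}
    for cid in comp_ids[k:]:
        n_t = 1 + int(min(rng_ct.zipf(1.8), 20))
        wts = np.array([ct_degree[t] for t in non_eis_pool], dtype=float)
        picks = set(
            rng_ct.choice(non_eis_pool, size=min(n_t, len(non_eis_pool)), replace=False, p=wts / wts.sum())
        )
        if decoy_cap >= 1 and rng_ct.random() < 0.5:
            n_eis = int(rng_ct.integers(1, decoy_cap + 1))
            picks |= set(rng_ct.choice(coverable, size=n_eis, replace=False))
        for t in sorted(picks):
            ct_rows.append((cid, t))
            if t in ct_degree:
                ct_degree[t] += 1
    # coverage fix-up: every target gene needs >= 1 passing-component edge
    covered_by_passing = {t for c, t in ct_rows if c in passing}
    passing_decoys = [c for c in passing if c not in planted_ids]
    for t in target_genes:
        if t not in covered_by_passing:
            cid = str(rng_ct.choice(passing_decoys))
            if t in eis.graph and t not in coverable:
                pass  # cannot happen: coverable == EIS ∩ targets
            ct_rows.append((cid, t))
    ct_edges = pd.DataFrame(sorted(set(ct_rows)), columns=["source", "target"])

    # --- gene sets tied to hub modules --------------------------------------
    # background-only genes widen the ORA universe beyond the network, the
    # way genome-wide annotation collections dwarf any one query list
    background = [f"B{i:04d}" for i in range(500)]
    coll = GeneSetCollection(name="synthetic")
    module_members: dict[str, list[str]] = {}
    for h in hubs:
        members = sorted({h, *ppi.neighbors(h)})
        noise = rng_gmt.choice(background, size=2, replace=False)
        coll.sets[f"MOD_{h}"] = (f"module around {h}", frozenset(members) | frozenset(noise))
        module_members[f"MOD_{h}"] = members
    pool = genes + background
    for i in range(params.n_random_terms):
        size = int(rng_gmt.integers(8, 26))
        members = frozenset(rng_gmt.choice(pool, size=size, replace=False))
        coll.sets[f"RND_{i:03d}"] = (f"random set {i}", members)
    coll.sets["BACKGROUND"] = ("universe padding", frozenset(background))

    # --- signaling graph with planted chain ---------------------------------
    signaling, chain = generate_signaling(params, rng=rng_sig)

    ppi_edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in ppi.edges), columns=["source", "target"])
    planted_coverage = len(coverable) / len(eis_nodes)
    ledger = {
        "seed": seed,
        "params": dataclasses.asdict(params),
        "planted_hubs": hubs,
        "planted_cover": planted_ids,
        "planted_cover_chunk_sizes": sizes,
        "planted_cover_coverage": planted_coverage,
        "planted_chain": list(chain),
        "eis_nodes": eis_nodes,
        "n_eis_nodes": len(eis_nodes),
        "coverable_eis_targets": len(coverable),
        "adme_violations": dict(sorted(violations.items())),
        "expected_kept_components": params.n_components - len(violations),
        "ct_degree_per_component": {
            c: int(n) for c, n in ct_edges.groupby("source").size().items()
        },
        "n_ct_edges": int(len(ct_edges)),
        "n_ppi_edges": int(len(ppi_edges)),
        "n_genes": len(genes),
        "pathogenic_only": sorted(pathogenic_only),
        "term_modules": module_members,
    }
    bundle = SyntheticBundle(
        params=params,
        seed=seed,
        components=components,
        ct_edges=ct_edges,
        ppi_edges=ppi_edges,
        pathogenic=pathogenic,
        collection=coll,
        signaling=signaling,
        ledger=ledger,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    log.info(
        "synthetic bundle: %d components (%d violators), %d genes, %d CT edges, "
        "%d PPI edges, EIS %d nodes",
        params.n_components,
        len(violations),
        len(genes),
        len(ct_edges),
        len(ppi_edges),
        len(eis_nodes),
    )
    return bundle


def generate_signaling(
    params: SyntheticParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[nx.DiGraph, tuple[str, ...]]:
    """Layered random DAG plus a planted maximum-score chain.

    The planted chain is a standalone source→sink path whose nodes are
    all in TG ∩ PG with the extreme NV/NC values, so after min–max
    normalization every chain node contributes the maximum per-node term
    and the chain attains the highest normalized MTW score among all
    source–sink cascades.  Returns (annotated graph, chain nodes).
    """
    params = params or SyntheticParams()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    g = nx.DiGraph()
    layers = [
        [f"N{l}_{w:02d}" for w in range(params.layer_width)]
        for l in range(params.n_layers)
    ]
    for l in range(params.n_layers - 1):
        for u in layers[l]:
            out = [v for v in layers[l + 1] if rng.random() < params.p_forward]
            if not out:  # every non-terminal node must reach the next layer
                out = [str(rng.choice(layers[l + 1]))]
            g.add_edges_from((u, v) for v in out)
    for v in (n for layer in layers for n in layer):
        g.add_node(v)

    chain = tuple(f"P{i:02d}" for i in range(params.chain_len))
    nx.add_path(g, chain)

    nv_hi, nc_hi = 40, 30
    pg_nv: dict[str, int] = {v: nv_hi for v in chain}
    nc: dict[str, int] = {v: nc_hi for v in chain}
    tg: set[str] = set(chain)
    dag_nodes = [n for layer in layers for n in layer]
    partial_pg = rng.choice(dag_nodes, size=4, replace=False)
    for v in partial_pg:
        pg_nv[str(v)] = int(rng.integers(1, 9))  # <= 0.2 of nv_hi after scaling
    partial_tg = rng.choice([n for n in dag_nodes if n not in pg_nv], size=4, replace=False)
    for v in partial_tg:
        tg.add(str(v))
        nc[str(v)] = int(rng.integers(0, 7))  # <= 0.2 of nc_hi after scaling
    annotated = annotate_signaling_graph(g, tg=tg, pg_nv=pg_nv, nc=nc)
    return annotated, chain
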