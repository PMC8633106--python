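"""End-to-end pipeline: screen → network → importance → EIS → CGFC → MTW → enrich.

`RunConfig` validates a YAML run description up front (unknown keys and
missing input files are errors before any stage runs); `run_all`
executes the stages, serializes every stage's output under the run
directory, and writes a manifest with per-stage counts so a rerun with
the same config is bit-identical apart from nothing — no timestamps are
recorded.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import adme, cgfc, importance, mtw, network
from .enrich import enrich as enrich_genes
from .enrich import significant_terms, term_coverage
from .io import dump_json, read_component_table, read_edges, read_gmt, read_pathogenic_table

__all__ = ["RunConfig", "StageFailure", "run_all"]

log = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    components: str
    ct_edges: str
    ppi_edges: str
    pathogenic: str
    genesets: str
    out_dir: str
    signaling_edges: str | None = None
    signaling_nodes: str | None = None
    disease_label: str = "disease"
    rules: dict = field(default_factory=dict)
    eis_mode: str = "strict"
    cgfc_mode: str = "greedy"
    cgfc_threshold: float = 0.95
    knapsack_budget: float | None = None
    knapsack_resolution: float = 1e-3
    mtw_threshold: float = 0.7
    mtw_score: str = "normalized"
    alpha: float = 0.05
    significance: str = "raw"
    expand_ppi: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = {
            "components": self.components,
            "ct_edges": self.ct_edges,
            "ppi_edges": self.ppi_edges,
            "pathogenic": self.pathogenic,
            "genesets": self.genesets,
        }
        optional = {
            "signaling_edges": self.signaling_edges,
            "signaling_nodes": self.signaling_nodes,
        }
        for key, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config key {key!r}: no such file: {p}")


def run_all(config: RunConfig) -> dict:
    """Run every stage; return the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                summary = fn()
            except Exception as exc:  # partial outputs stay on disk
                dump_json(out / "manifest.json", manifest)
                raise StageFailure(name, exc) from exc
            manifest["stages"][name] = summary
            log.info("stage %s: %s", name, summary)
            return summary

        return deco

    state: dict = {}

    @stage("screen")
    def _screen():
        records = read_component_table(config.components)
        rules = adme.AdmeRuleSet(**config.rules)
        kept, verdicts = adme.screen_components(records, rules)
        verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
        state["kept"] = kept
        return {"n_components": len(records), "n_kept": len(kept)}

    @stage("build-net")
    def _build():
        kept_ids = {c.component_id for c in state["kept"]}
        ct = read_edges(config.ct_edges)
        ct = ct[ct["source"].isin(kept_ids)].reset_index(drop=True)
        ppi = read_edges(config.ppi_edges)
        pathogenic = read_pathogenic_table(config.pathogenic)
        ct_net = network.build_ct_network(state["kept"], ct)
        ctpd = network.assemble_ctpd(
            ct_net, ppi, pathogenic, config.disease_label, expand_ppi=config.expand_ppi
        )
        tp = network.extract_tp(ctpd)
        state.update(ct=ct, pathogenic=pathogenic, ctpd=ctpd, tp=tp)
        return {
            "ctpd_nodes": ctpd.number_of_nodes(),
            "ctpd_edges": ctpd.number_of_edges(),
            "tp_nodes": tp.number_of_nodes(),
            "tp_edges": tp.number_of_edges(),
        }

    @stage("importance")
    def _importance():
        table = importance.node_importance(state["tp"], graph_id="tp")
        table.to_tsv(out / "importance.tsv")
        state["im"] = table
        return {
            "eff_diameter": table.eff_diameter,
            "im_median": table.im_median,
            "n_nodes": len(table.scores),
        }

    @stage("eis")
    def _eis():
        eis = importance.extract_eis(state["tp"], state["im"], mode=config.eis_mode)
        targets = {
            n for n, d in state["tp"].nodes(data=True) if "target" in d["roles"]
        }
        pathogenic_set = {p.symbol for p in state["pathogenic"]}
        importance.categorize_nodes(eis, targets, pathogenic_set)
        dump_json(out / "eis.json", eis.to_json_dict())
        state.update(eis=eis, targets=targets, pathogenic_set=pathogenic_set)
        return {
            "eis_nodes": eis.graph.number_of_nodes(),
            "eis_edges": eis.graph.number_of_edges(),
            "categories": eis.category_counts(),
        }

    @stage("cgfc")
    def _cgfc():
        tmap = cgfc.component_target_map(state["ct"])
        selection = cgfc.greedy_coverage_curve(tmap, state["eis"])
        if config.cgfc_mode == "greedy":
            cgfc.select_cgfc(selection, config.cgfc_threshold)
        else:
            items = cgfc.compute_items(state["eis"], tmap, state["pathogenic_set"])
            budget = config.knapsack_budget
            if budget is None:
                raise ValueError("knapsack mode needs knapsack_budget")
            chosen, objective = cgfc.knapsack_select(
                items, budget, config.knapsack_resolution
            )
            selection.selected = sorted(chosen)
            selection.mode = "knapsack"
            selection.objective = objective
        dump_json(out / "cgfc.json", selection.to_json_dict())
        state["selection"] = selection
        return {
            "mode": selection.mode,
            "n_selected": len(selection.selected),
            "final_coverage": selection.cumulative[-1] if selection.cumulative else 0.0,
        }

    if config.signaling_edges:

        @stage("mtw")
        def _mtw():
            sig_edges = read_edges(config.signaling_edges)
            import networkx as nx

            g = nx.DiGraph()
            g.add_edges_from(zip(sig_edges["source"], sig_edges["target"]))
            if config.signaling_nodes:
                nodes = pd.read_csv(config.signaling_nodes, sep="\t", dtype=str)
                tg = set(nodes.loc[nodes["in_tg"].astype(int) == 1, "node"])
                pg_nv = {
                    r.node: int(r.nv)
                    for r in nodes.itertuples()
                    if int(r.in_pg) == 1
                }
                nc = {r.node: int(r.nc) for r in nodes.itertuples()}
            else:
                tg = state["targets"]
                pg_nv = {p.symbol: p.nv for p in state["pathogenic"]}
                nc = {
                    n: int(d.get("nc", 0)) for n, d in state["tp"].nodes(data=True)
                }
            g = mtw.annotate_signaling_graph(g, tg=tg, pg_nv=pg_nv, nc=nc)
            ctx = mtw.ScoreContext.from_graph(g)
            paths = mtw.shortest_cascades(g)
            scored = [mtw.score_cascade(p, g, ctx) for p in paths]
            retained = mtw.retain_cascades(
                scored, config.mtw_threshold, score=config.mtw_score
            )
            modules = mtw.merge_modules(retained, graph=g) if retained else []
            dump_json(
                out / "cascades.json",
                {
                    "r_avg": ctx.r_avg,
                    "d_avg": ctx.d_avg,
                    "cascades": [
                        {
                            "chain": p.label(),
                            "raw": p.raw,
                            "normalized": p.normalized,
                            "retained": p.retained,
                        }
                        for p in sorted(scored, key=lambda q: -q.normalized)
                    ],
                    "modules": [sorted(m.nodes) for m in modules],
                },
            )
            state["retained"] = retained
            return {
                "n_cascades": len(scored),
                "n_retained": len(retained),
                "n_modules": len(modules),
            }

    @stage("enrich")
    def _enrich():
        collection = read_gmt(config.genesets)
        selected = set(state["selection"].selected)
        tmap = cgfc.component_target_map(state["ct"])
        cgfc_targets = set().union(*(tmap.get(c, frozenset()) for c in selected)) if selected else set()
        results = enrich_genes(
            cgfc_targets,
            collection,
            alpha=config.alpha,
            significance=config.significance,  # type: ignore[arg-type]
        )
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        pg_terms = significant_terms(
            enrich_genes(state["pathogenic_set"], collection, alpha=config.alpha)
        )
        sig = significant_terms(results)
        coverage = term_coverage(pg_terms, sig) if pg_terms else float("nan")
        return {
            "n_terms_tested": len(results),
            "n_significant": len(sig),
            "coverage_of_pathogenic_terms": coverage,
        }

    dump_json(out / "manifest.json", manifest)
    return manifest
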