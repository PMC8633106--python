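# netpharm

A network-pharmacology toolkit for optimizing multi-component herbal
formulas against a complex disease.  It was built around the
Chai-Hu-Shu-Gan-San (CHSGS) → depression case study: starting from a
component property table, predicted component–target edges, a
protein–protein interaction (PPI) layer, and literature-supported
pathogenic genes, the pipeline isolates the *core group of functional
components* (CGFC) — the small component subset whose targets cover most
of the proteins through which the formula's effect can actually reach the
disease — and then scores receptor-to-effector signaling cascades to
propose mechanism chains.

Who it is for: computational pharmacologists and systems biologists who
already have component/target/PPI/disease-gene tables (from TCMSP,
DisGeNET, STRING, and similar resources) and want a reproducible,
scriptable implementation of the screening → network → selection →
mechanism workflow, with every stage exposed as a library function and a
CLI subcommand.

## The model

**1. ADME screen.**  Components are kept when they jointly satisfy
MW < 500 Da, Hdon ≤ 5, Hacc ≤ 10, rotatable bonds ≤ 10, −2 < logP < 5,
oral bioavailability ≥ 30 %, plus (when predicted classes are supplied)
high GI absorption, no high-level hERG inhibition, and negative
carcinogenicity.  The hydrogen-bond thresholds are inclusive: quercetin,
with exactly five donors, is a canonical active flavonol.

**2. CTPD network.**  Kept components and their targets form the C-T
layer; PPI edges are overlaid between genes already present as targets or
pathogenic genes; each pathogenic gene links to the single disease node.
The gene-only slice with PPI edges is the T-P subnetwork.

**3. Node importance and the effective intervention space (EIS).**
For node *i* in the T-P network with effective diameter ∅ (largest finite
hop distance, across components if disconnected):

```
IM_i = ((∅ + 1) − L_i) / ∅  ×  B_i / (n(n−1)/2)
```

where `L_i` is the mean length of shortest paths transiting *i* and
`B_i = Σ_{j<k} g_jk(i)/g_jk` is the transit-betweenness sum (fraction of
the pair's geodesics through *i*).  Nodes with `IM > median(IM)` and
their mutual edges form the EIS; its members — the intervention-response
proteins — are categorized as essential-common (target ∩ pathogenic),
disease-specific, or component-specific.

**4. CGFC selection (CCC model).**  Each component *i* gets a coverage
weight `w_i = |targets(i) ∩ EIS| / |EIS|` and a value
`v_i` = fraction of EIS pathogenic genes within one EIS hop of its
targets.  The default selector adds components best-first by marginal
EIS coverage and cuts the accumulative curve at 95 % of attainable
coverage; a 0/1-knapsack mode maximizes `Σ v_i x_i` subject to
`Σ w_i x_i ≤ R` by exact dynamic programming on a discretized weight
grid.

**5. Maximum targeting weight (MTW).**  On a directed signaling graph,
each Dijkstra-shortest receptor→effector path is scored per node by
`IM_i + R_i + D_i ± R_avg ± D_avg`, where `R_i` min–max-normalizes the
literature evidence over pathogenic genes, `D_i` the regulating-component
count over targets, and the signs reward membership in the pathogenic
(±R_avg) and target (±D_avg) sets.  The reported score is the per-node
mean; cascades scoring > 0.7 are retained and merged into mechanism
modules (cascades sharing a signaling edge merge together).

**6. Enrichment.**  One-sided hypergeometric over-representation against
user-supplied GMT collections (raw p < 0.05 by default, BH-adjusted mode
available), plus term-coverage comparison between gene lists and a
benchmark of IM against degree/betweenness/closeness/clustering/
neighborhood-connectivity baselines.

## Worked example

Audit the bundled 71-member CHSGS core component table against the
default rule set:

```python
>>> from netpharm.datasets import load_cgfc_components
>>> from netpharm import screen_components
>>> kept, verdicts = screen_components(load_cgfc_components())
>>> len(kept)
71
>>> verdicts.loc[verdicts.component_id == "CHSGS2", ["hdon", "passed"]]
   hdon  passed
0  True    True
```

All 71 published core components pass — including quercetin (CHSGS2) on
the inclusive Hdon ≤ 5 boundary.  Run the whole pipeline on a seeded
synthetic bundle:

```bash
netpharm simulate --seed 1 --out demo/bundle
netpharm run-all --config demo/run.yaml
```

with `demo/run.yaml` pointing at the bundle's files and an output
directory.  The run prints one summary per stage:

```
screen: {'n_components': 200, 'n_kept': 142}
build-net: {'ctpd_nodes': 443, 'ctpd_edges': 1457, 'tp_nodes': 300, 'tp_edges': 310}
importance: {'eff_diameter': 12, 'im_median': 0.0, 'n_nodes': 300}
eis: {'eis_nodes': 100, 'eis_edges': 110, 'categories': {'essential_common': 34, 'disease_specific': 17, 'component_specific': 49}}
cgfc: {'mode': 'greedy', 'n_selected': 7, 'final_coverage': 0.83}
mtw: {'n_cascades': 16, 'n_retained': 1, 'n_modules': 1}
enrich: {'n_terms_tested': 26, 'n_significant': 11, 'coverage_of_pathogenic_terms': 1.0}
```

Reading it: 58 of 200 synthetic components fail exactly one ADME rule;
the T-P network of 300 genes has effective diameter 12; 100 genes clear
the median-IM threshold into the EIS; greedy selection finds the 7
components planted by the generator as the minimal cover (83 % of the
EIS is coverable at all); one cascade — the planted maximum-attribute
chain — survives the 0.7 score filter; and the selected components'
targets recover all significantly enriched pathogenic-gene terms.

## Layout

| module | contents |
| --- | --- |
| `netpharm.io` | TSV/GMT/edge-table readers and writers, domain records |
| `netpharm.adme` | rule set, per-component verdicts, screening |
| `netpharm.network` | C-T / CTPD assembly, T-P extraction, evidence binning |
| `netpharm.importance` | ∅, IM, baseline centralities, EIS, categorization |
| `netpharm.cgfc` | knapsack items, DP selector, greedy accumulative curve |
| `netpharm.mtw` | normalizations, Dijkstra cascades, scoring, module merge |
| `netpharm.enrich` | hypergeometric ORA, BH adjustment, coverage benchmark |
| `netpharm.synthetic` | seeded bundle generator with planted ground truths |
| `netpharm.pipeline` / `netpharm.cli` | run-config, stage chaining, CLI |

See `docs/methods.md` for the modeling choices, parameter meanings, and
known limitations.
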