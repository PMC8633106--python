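# Methods

This note records how netpharm defines each quantity it computes, the
choices made where the formulation was genuinely open, and what the
bundled synthetic data can and cannot establish.

## Node importance (IM)

For a simple undirected graph with `n ≥ 3` nodes, let ∅ be the effective
diameter: the largest finite hop distance, taken as the maximum over
connected components when the graph is disconnected (isolated nodes
contribute 0; a graph with no edges has no defined importance).  For a
node *i*,

```
IM_i = ((∅ + 1) − L_i) / ∅ × B_i / (n(n−1)/2)
```

* Pair summation runs over **unordered pairs {j, k} with j ≠ i ≠ k**
  (the transit convention of classical betweenness).  Counting endpoint
  pairs would give leaves positive importance, which contradicts the
  metric's purpose of surfacing hub/broker nodes.
* `L_i` is the **mean length of shortest paths passing through i**:
  when a pair has several geodesics, each geodesic through *i* counts
  separately in both the numerator (its length) and the denominator
  (the path count `m`).  `IM_i = 0` whenever `m = 0`.
* `B_i = Σ g_jk(i)/g_jk`, the sum of per-pair geodesic fractions
  carried by *i*.  Pairs in different components have no geodesic and
  contribute nothing.
* The normalization `n(n−1)/2` (rather than betweenness' `(n−1)(n−2)/2`)
  is kept as specified; it makes the second factor — and hence IM —
  strictly smaller than 1.
* Since every transit path has length in `[2, ∅]`, the first factor lies
  in `[1/∅, (∅−1)/∅]`; together `0 ≤ IM_i < 1`.
* The global ∅ is used in the first factor even for disconnected
  graphs; per-component diameters are not substituted.

The implementation computes all-pairs BFS distances and geodesic counts
once, then evaluates all three per-node sums with vectorized pair masks
(`O(n³)` work, exact, no sampling).  Tests verify equality with an
independent geodesic-enumeration oracle to 1e-12 on the complete
non-isomorphic graph atlas up to 7 nodes and on random 8- and 30-node
graphs.

## Effective intervention space

Nodes with `IM` strictly above the median IM of the T-P network are
kept; the EIS is their induced subgraph.  Strict `>` means median ties
are excluded deterministically — no tie-breaking randomness; a `ge`
mode admits ties, which matters only when many scores coincide (for
instance graphs where over half the nodes have IM = 0 *and* the median
is positive).  An EIS that would be empty (all scores equal) is an
error rather than a silent empty result.  Categories partition the EIS:
essential-common (target and pathogenic), disease-specific (pathogenic
only), component-specific (target only); a node in neither set cannot
occur if the T-P construction is correct and is treated as an error.

## CTPD assembly conventions

* PPI edges are restricted to genes already present as targets or
  pathogenic genes.  An `expand_ppi` option admits first neighbors; the
  default stays restricted because the intervention space is about
  relaying effect between the two existing gene layers, not importing
  an interactome.
* The graph is simple: where layers would doubly connect a pair, type
  precedence CT > GD > PPI decides the surviving label (the IM formula
  assumes a simple graph).
* Gene matching is exact-string and case-sensitive; unmatched PPI rows
  are counted and logged, never fatal.  Identifier normalization is out
  of scope and must happen upstream.
* Pathogenic genes absent from both the target list and the PPI file
  remain as isolated T-P nodes and are excluded from ∅ by the
  disconnected-graph rule.

## ADME screen

Defaults: MW < 500, Hdon ≤ 5, Hacc ≤ 10, RBN ≤ 10, −2 < logP < 5,
OB ≥ 30 %.  The donor/acceptor bounds are **inclusive**: the published
core-component table itself contains quercetin with Hdon = 5, so an
exclusive reading would reject a component the reference output keeps.
`strict_hbond` restores the open comparison.  Categorical rules
(GI = high required, hERG = high excluded, carcinogenicity = negative
required) apply only when the upstream predictor supplied a value;
`unknown` skips the rule by default (`unknown_policy="fail"` inverts
this).  The overall verdict is the conjunction of enabled rules — no
"rescue if only one Lipinski criterion fails" variant.

## CGFC selection

`w_i` and `v_i` have no operational definition in the source
formulation; netpharm defines them so that the accumulative curve's
y-axis is exactly "coverage of intervention-response proteins":

* `w_i = |targets(i) ∩ EIS| / |EIS|`;
* `v_i` = fraction of EIS pathogenic genes within one EIS hop of the
  component's EIS targets (targets themselves included).  Components
  with no EIS target, or with zero pathogenic reach, are dropped from
  the knapsack item list with a log note.

The greedy selector is best-first on marginal coverage gain with
lexicographic tie-breaking (fully deterministic), which makes the gain
sequence non-increasing and the final cumulative value equal to the
total attainable coverage regardless of order.  The default stopping
threshold is 0.95 of EIS coverage.  The knapsack mode solves the stated
0/1 program exactly by DP after scaling weights to a 1/1000 grid
(round half up) — a documented approximation knob, with per-item
rounding error below half a grid step.  The two modes answer different
questions (cheapest high coverage vs. best value under a budget `R`);
no value of `R` is built in because none is given by the source
formulation.

## MTW cascade scoring

Sources default to in-degree-0 nodes (extracellular receptors), sinks
to out-degree-0 nodes; both can be supplied explicitly.  Edge weights
default to 1, and Dijkstra is used so user-supplied weights work
unchanged.  Among equal-weight shortest paths the lexicographically
smallest node sequence is chosen, making runs reproducible.

The per-node term is `IM_i + R_i + D_i ± R_avg ± D_avg` with `+R_avg`
iff the node is a pathogenic gene and `+D_avg` iff it is a target.
`R_i`/`D_i` min–max-normalize NV over pathogenic genes and NC over
targets; values outside the normalization band clip into [0, 1], and a
degenerate band (max = min) maps to 0 — no spread carries no signal.
The raw score is a sum and grows with path length, while the published
score scale is bounded in [0.70, 0.96]; netpharm therefore reports both
the raw sum and the **per-node mean**, applies the retention threshold
(default 0.7, strictly greater) to the mean by default, and makes the
choice explicit (`score="raw"|"normalized"`).  Reproduction of the
published score values themselves is not claimed — they depend on the
exact integrated pathway graph and attribute snapshot.

Module merging links cascades transitively when they **share a directed
edge**; a shared node alone does not merge.  Rationale: two mechanism
modules may converge on one downstream effector (the published pair of
modules both reach FOS) without sharing any signaling step; node-based
merging would collapse them into one.  `by="node"` restores the
coarser behavior.  IM for signaling nodes is computed on the undirected
view of the signaling graph itself.

## Enrichment

One-sided hypergeometric upper-tail p per term, universe defaulting to
the union of collection genes (an explicit universe can be passed);
query genes outside the universe are dropped with a warning, and set
members are intersected with the universe so N, K, n, k live in one
space.  Significance defaults to raw p < 0.05 to match the reference
workflow's stated cut-off; BH-adjusted calling is available.  No
gene-set size filters are applied by default.  The method benchmark
builds its reference as the terms significant in both the full target
list and the pathogenic list, then reports each scoring method's
coverage of that reference after median-thresholding its scores.

## Synthetic data: what it emulates, and what it does not

The generator produces deterministic bundles (one master seed fans out
to per-section seeds; identical seed+parameters give byte-identical
files).  Default sizes — 200 components, 300 genes, 160 pathogenic
genes, 7 herbs — keep the full pipeline under a few seconds while
leaving every stage non-trivial.

Planted ground truths are **constructive, not statistical**:

* *Hubs.*  The PPI layer grows by preferential attachment from a ring
  of 10 hub genes, each anchored by two dedicated leaves.  Hubs are cut
  vertices (IM > 0) while most genes are leaves (IM = 0), so the median
  IM is 0 and the hub set provably lands in the EIS.
* *Minimal cover.*  The generator computes the EIS itself, splits the
  coverable EIS targets into strictly decreasing chunks assigned to 7
  planted components, and caps every decoy's EIS-target count below the
  smallest chunk, so best-first selection must pick the planted
  components first and exactly.
* *Top cascade.*  A standalone source→sink chain whose nodes carry
  maximal NV/NC and dual TG∩PG membership outranks every other cascade
  by at least the membership-correction margin.

Violating components fail exactly one randomly chosen rule, so the
expected kept count is exact.  ADME properties, evidence counts
(truncated Zipf, a = 2.2, max 50) and herb membership are otherwise
independent draws — the generator does not emulate chemical series,
correlated ADME properties, PPI confidence scores, literature bias
toward well-studied genes, or curated pathway topology.  Passing the
planted-recovery tests therefore demonstrates algorithmic correctness
under the stated constructions, not performance on real databases.

Gene-set terms cover hub neighborhoods plus random sets over a widened
universe (500 background-only genes), mimicking the way genome-scale
annotation collections dwarf any single query list.

## Numerical and degenerate-input choices

* Diameter of a < 2-node graph, importance of a < 3-node or edgeless
  graph, empty EIS, empty reference term list, and an empty universe
  are errors, not sentinel values.
* Knapsack with budget 0, or below the smallest weight, returns an
  empty selection with objective 0.
* Median uses the standard mean-of-two-middles for even n.
* All orderings (node lists, greedy ties, cascade ties, JSON keys) are
  made deterministic by sorting; no stage consumes randomness outside
  the synthetic generator.

## Known limitations

* The signaling graph treats second messengers (cAMP, DAG) as ordinary
  nodes and ignores activation vs. inhibition signs.
* IM is exact `O(n³)`; graphs beyond ~10⁴ nodes would need a sampled
  betweenness variant, which is deliberately out of scope.
* No identifier mapping: symbol mismatches silently reduce overlap
  (logged where detectable).
* The knapsack weight grid trades exactness for speed at resolution
  1/1000; pass a finer resolution if weights are near-degenerate.
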