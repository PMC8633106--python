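"""Core group of functional components (CGFC) selection.

Each screened component *i* becomes a knapsack item with

* weight ``w_i`` — the fraction of EIS nodes among its targets, and
* value ``v_i`` — the fraction of EIS pathogenic genes it can reach,
  counting its EIS targets and their first neighbors inside the EIS.

Two selectors are provided.  The cumulative-contribution (greedy)
selector repeatedly adds the component with the largest marginal gain in
EIS-node coverage, records the accumulative coverage curve, and cuts the
curve at a coverage threshold (default 0.95).  The 0/1-knapsack selector
maximizes the summed value subject to a total-weight budget ``R`` by
dynamic programming on a discretized weight grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .importance import EffectiveInterventionSpace

__all__ = [
    "KnapsackItem",
    "CGFCSelection",
    "component_target_map",
    "compute_items",
    "knapsack_select",
    "greedy_coverage_curve",
    "select_cgfc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnapsackItem:
    """Coverage weight and pathogenic-reach value of one component."""

    component_id: str
    w: float
    v: float

    def __post_init__(self) -> None:
        if not 0 < self.w <= 1:
            raise ValueError(f"{self.component_id}: w must be in (0, 1], got {self.w}")
        if not 0 < self.v <= 1:
            raise ValueError(f"{self.component_id}: v must be in (0, 1], got {self.v}")


@dataclass
class CGFCSelection:
    """Ordered selection trace: marginal gains, cumulative coverage, cut."""

    order: list[str]
    gains: list[float]
    cumulative: list[float]
    selected: list[str] = field(default_factory=list)
    mode: str = "greedy"
    objective: float | None = None  # knapsack mode only

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component_id": self.order,
                "gain": self.gains,
                "cumulative_coverage": self.cumulative,
                "selected": [c in set(self.selected) for c in self.order],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "order": self.order,
            "gains": self.gains,
            "cumulative_coverage": self.cumulative,
            "selected": self.selected,
            "objective": self.objective,
        }


def component_target_map(ct_edges: pd.DataFrame) -> dict[str, frozenset[str]]:
    """component id -> set of predicted target genes, from a CT edge table."""
    out: dict[str, set[str]] = {}
    for row in ct_edges.itertuples(index=False):
        out.setdefault(row.source, set()).add(row.target)
    return {c: frozenset(t) for c, t in out.items()}


def compute_items(
    eis: EffectiveInterventionSpace,
    targets_by_component: Mapping[str, frozenset[str]],
    pathogenic_set: set[str] | frozenset[str],
) -> list[KnapsackItem]:
    """Score each component over the EIS.

    ``w_i = |targets(i) ∩ EIS| / |EIS|``.  ``v_i`` is the fraction of
    EIS pathogenic genes within one EIS hop of the component's EIS
    targets (the targets themselves included).  Components with no
    target inside the EIS are dropped with a log note.
    """
    eis_nodes = set(eis.graph.nodes)
    if not eis_nodes:
        raise ValueError("empty EIS")
    pg_in_eis = eis_nodes & set(pathogenic_set)
    if not pg_in_eis:
        raise ValueError("EIS contains no pathogenic genes; v_i undefined")
    items: list[KnapsackItem] = []
    dropped = no_reach = 0
    for comp in sorted(targets_by_component):
        hit = targets_by_component[comp] & eis_nodes
        if not hit:
            dropped += 1
            continue
        reach = set(hit)
        for t in hit:
            reach.update(eis.graph.neighbors(t))
        v = len(reach & pg_in_eis) / len(pg_in_eis)
        if v == 0:
            no_reach += 1
            continue
        items.append(KnapsackItem(component_id=comp, w=len(hit) / len(eis_nodes), v=v))
    if dropped or no_reach:
        log.info(
            "compute_items: dropped %d components with no EIS target, "
            "%d with no pathogenic reach",
            dropped,
            no_reach,
        )
    return items


def knapsack_select(
    items: Sequence[KnapsackItem], R: float, resolution: float = 1e-3
) -> tuple[set[str], float]:
    """0/1 knapsack: maximize sum(v_i x_i) s.t. sum(w_i x_i) <= R.

    Weights are discretized to multiples of ``resolution`` (round half
    up) before the exact DP — an approximation knob, not a heuristic:
    with the default grid of 1/1000 the rounding error per item is below
    half a grid step.  Returns the selected component ids and the
    objective value (sum of the *original* v over selected items).
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    if R == 0 or not items:
        return set(), 0.0
    wi = [int(np.floor(it.w / resolution + 0.5)) for it in items]
    cap = int(np.floor(R / resolution + 1e-9))
    if cap <= 0 or all(w > cap for w in wi):
        return set(), 0.0
    n = len(items)
    # DP over capacity; value table in float, choices for reconstruction
    best = np.zeros(cap + 1)
    take = np.zeros((n, cap + 1), dtype=bool)
    for i in range(n):
        w, v = wi[i], items[i].v
        if w > cap:
            continue
        cand = best[: cap - w + 1] + v
        upd = cand > best[w:] + 1e-15
        take[i, w:] = upd
        best[w:] = np.where(upd, cand, best[w:])
    # reconstruct, iterating items backwards
    chosen: set[str] = set()
    c = int(np.argmax(best))
    for i in range(n - 1, -1, -1):
        if take[i, c]:
            chosen.add(items[i].component_id)
            c -= wi[i]
    objective = sum(it.v for it in items if it.component_id in chosen)
    return chosen, objective


def greedy_coverage_curve(
    targets_by_component: Mapping[str, frozenset[str]],
    eis: EffectiveInterventionSpace,
) -> CGFCSelection:
    """Best-first accumulative coverage of EIS nodes.

    At each step the component with the largest marginal gain in
    ``|union of selected targets ∩ EIS| / |EIS|`` is appended (ties
    broken lexicographically by component id); the curve records the
    cumulative coverage after each addition.  Components whose EIS
    targets are already covered contribute gain 0 but still appear in
    the ordering, so the final cumulative value is the total attainable
    coverage.
    """
    eis_nodes = frozenset(eis.graph.nodes)
    n_eis = len(eis_nodes)
    remaining = {
        c: targets_by_component[c] & eis_nodes for c in sorted(targets_by_component)
    }
    remaining = {c: t for c, t in remaining.items() if t}
    order: list[str] = []
    gains: list[float] = []
    cumulative: list[float] = []
    covered: set[str] = set()
    while remaining:
        best = min(remaining, key=lambda c: (-len(remaining[c] - covered), c))
        gain = len(remaining[best] - covered)
        covered |= remaining[best]
        del remaining[best]
        order.append(best)
        gains.append(gain / n_eis)
        cumulative.append(len(covered) / n_eis)
    return CGFCSelection(order=order, gains=gains, cumulative=cumulative, mode="greedy")


def select_cgfc(selection: CGFCSelection, threshold: float = 0.95) -> list[str]:
    """Shortest curve prefix whose cumulative coverage reaches the threshold.

    If the threshold is unreachable, returns every contributing component
    (positive marginal gain) with a warning.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for i, cov in enumerate(selection.cumulative):
        if cov >= threshold:
            selection.selected = selection.order[: i + 1]
            return selection.selected
    log.warning(
        "coverage threshold %.3f unreachable (max %.3f); returning all contributors",
        threshold,
        selection.cumulative[-1] if selection.cumulative else 0.0,
    )
    selection.selected = [c for c, g in zip(selection.order, selection.gains) if g > 0]
    return selection.selected
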