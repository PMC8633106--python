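"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity by direct enumeration — geodesic
listing, subset enumeration, exact rational tail sums — sharing no code
with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def im_oracle(graph: nx.Graph) -> dict:
    """Node importance by exhaustive geodesic enumeration.

    For every unordered node pair, list all shortest paths; a path
    transits i when i is interior.  IM combines the mean transit-path
    length (diameter-normalized) with the pair-normalized fraction of
    geodesics carried.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    eff_d = 0
    all_paths: dict[tuple, list[list]] = {}
    for j, k in itertools.combinations(nodes, 2):
        if nx.has_path(graph, j, k):
            paths = list(nx.all_shortest_paths(graph, j, k))
            all_paths[(j, k)] = paths
            eff_d = max(eff_d, len(paths[0]) - 1)
    out = {}
    for i in nodes:
        m = 0
        sum_len = 0
        frac = 0.0
        for (j, k), paths in all_paths.items():
            if i in (j, k):
                continue
            through = [p for p in paths if i in p[1:-1]]
            if through:
                m += len(through)
                sum_len += sum(len(p) - 1 for p in through)
                frac += len(through) / len(paths)
        if m == 0 or eff_d == 0:
            out[i] = 0.0
        else:
            first = ((eff_d + 1) - sum_len / m) / eff_d
            out[i] = first * frac / (n * (n - 1) / 2)
    return out


def diameter_oracle(graph: nx.Graph) -> int:
    """Max finite hop distance via all-pairs BFS."""
    best = 0
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        best = max(best, max(dists.values()))
    return best


def knapsack_oracle(weights, values, R) -> float:
    """Exhaustive 0/1 subset enumeration (n <= 20).

    Subset weight/value vectors are built by doubling: appending item i
    maps the 2^i existing subsets to 2^i new ones that include it.
    """
    w_all = np.zeros(1)
    v_all = np.zeros(1)
    for w, v in zip(weights, values):
        w_all = np.concatenate([w_all, w_all + w])
        v_all = np.concatenate([v_all, v_all + v])
    feasible = w_all <= R + 1e-12
    if not feasible.any():
        return 0.0
    return float(v_all[feasible].max())


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    denom = comb(N, n)
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)


def min_weight_path_oracle(graph: nx.DiGraph, s, t, weight="weight") -> float | None:
    """Minimum path weight by enumerating every simple path."""
    best = None
    for path in nx.all_simple_paths(graph, s, t):
        w = sum(graph.edges[u, v].get(weight, 1) for u, v in zip(path, path[1:]))
        if best is None or w < best:
            best = w
    return best


def greedy_cover_oracle(sets: dict, universe: frozenset) -> list:
    """Best-first set cover ordering, ties to the smallest key."""
    remaining = {k: frozenset(v) & universe for k, v in sets.items() if frozenset(v) & universe}
    covered: set = set()
    order = []
    while remaining:
        best = sorted(remaining, key=lambda c: (-len(remaining[c] - covered), c))[0]
        covered |= remaining.pop(best)
        order.append(best)
    return order
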