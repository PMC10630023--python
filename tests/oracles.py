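"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: betweenness is
computed by enumerating every shortest path, and hypergeometric tails by
summing binomial-coefficient ratios.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import networkx as nx


def brute_betweenness(net) -> dict[str, float]:
    """Exhaustive shortest-path betweenness, normalized per component by
    2/((nc-1)(nc-2))."""
    g = net.to_networkx()
    bc = dict.fromkeys(net.nodes, 0.0)
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        nc = len(comp)
        if nc < 3:
            continue
        raw = dict.fromkeys(comp, 0.0)
        for s, t in combinations(comp, 2):
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for v in path[1:-1]:
                    raw[v] += 1.0 / len(paths)
        scale = 2.0 / ((nc - 1) * (nc - 2))
        for v in comp:
            bc[v] = raw[v] * scale
    return bc


def brute_hypergeom_tail(overlap: int, background: int, term: int, query: int) -> float:
    """P(X >= overlap) by direct pmf summation."""
    if overlap <= 0:
        return 1.0
    denom = comb(background, query)
    total = 0
    for k in range(overlap, min(term, query) + 1):
        total += comb(term, k) * comb(background - term, query - k)
    return total / denom
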