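"""Dense-module detection in the style of molecular-complex detection (MCODE).

Vertices are weighted by (core-clustering coefficient) x (highest k-core
number) of their closed neighborhood; complexes grow greedily outward from
the highest-weight unvisited seed, admitting neighbors whose weight is
within a fractional cutoff of the seed weight; an optional haircut prunes
each complex to its 2-core.  Cluster score is density x size.

Defaults follow the published plugin defaults: degree cutoff 2, node score
cutoff 0.2, k-core 2, haircut on, fluff off.  Ties are broken
deterministically by (higher weight, higher degree, lexicographic id).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .network import Network


@dataclass(frozen=True)
class ModuleCluster:
    """A dense subgraph: member nodes, internal edge count, density
    (2e / n(n-1)) and score (density x size)."""

    nodes: frozenset[str]
    n_edges: int
    density: float
    score: float
    seed_node: str | None = None


def _closed_neighborhood(adj: Mapping[str, set], v: str) -> set[str]:
    return adj[v] | {v}


def _subgraph_density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def vertex_weights(net: Network, degree_cutoff: int = 2) -> dict[str, float]:
    """Per-node weight = core-clustering coefficient x highest k-core number
    of the node's closed neighborhood.

    The core-clustering coefficient is the density of the highest k-core of
    the closed-neighborhood subgraph.  Nodes with degree below
    ``degree_cutoff`` (and isolated nodes) get weight 0.
    """
    g = net.to_networkx()
    adj = net.adjacency()
    weights: dict[str, float] = {}
    for v in net.nodes:
        if len(adj[v]) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph(_closed_neighborhood(adj, v))
        core_numbers = nx.core_number(nbhd)
        k_max = max(core_numbers.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core_numbers.items() if c >= k_max]
        core = nbhd.subgraph(core_nodes)
        density = _subgraph_density(core.number_of_nodes(), core.number_of_edges())
        weights[v] = k_max * density
    return weights


def score_cluster(nodes: Iterable[str], net: Network) -> ModuleCluster:
    """Density x size score of the induced simple subgraph."""
    nodes = frozenset(nodes)
    if len(nodes) < 2:
        raise ValueError("cluster density undefined for fewer than 2 nodes")
    n_edges = sum(1 for a, b in net.edges if a in nodes and b in nodes)
    density = _subgraph_density(len(nodes), n_edges)
    return ModuleCluster(
        nodes=nodes,
        n_edges=n_edges,
        density=density,
        score=density * len(nodes),
    )


def find_complexes(
    net: Network,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_threshold: float = 0.2,
    k_core: int = 2,
    degree_cutoff: int = 2,
) -> list[ModuleCluster]:
    """Greedy seeded complex prediction.

    Seeds are taken in order of decreasing weight (ties: higher degree, then
    node id); expansion admits unvisited neighbors whose weight is at least
    ``seed_weight * (1 - node_score_cutoff)``.  Complexes lacking a
    ``k_core``-core are discarded; with ``haircut`` each complex is pruned
    to its 2-core.  Emitted clusters are node-disjoint and connected.
    """
    if not (0.0 <= node_score_cutoff <= 1.0):
        raise ValueError("node_score_cutoff must be in [0, 1]")
    weights = vertex_weights(net, degree_cutoff=degree_cutoff)
    adj = net.adjacency()
    deg = net.degrees()
    order = sorted(net.nodes, key=lambda v: (-weights[v], -deg[v], v))
    visited: set[str] = set()
    g = net.to_networkx()
    clusters: list[ModuleCluster] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            v = frontier.pop()
            for w in sorted(adj[v]):
                if w in visited:
                    continue
                if weights[w] >= threshold:
                    visited.add(w)
                    members.add(w)
                    frontier.append(w)
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        core_numbers = nx.core_number(sub)
        if max(core_numbers.values()) < k_core:
            continue
        if haircut:
            members = {v for v, c in core_numbers.items() if c >= 2}
            if len(members) < 2:
                continue
        if fluff:
            extra = set()
            for v in sorted(members):
                for w in sorted(adj[v]):
                    if w in members or w in extra:
                        continue
                    nbhd = g.subgraph(_closed_neighborhood(adj, w))
                    d = _subgraph_density(nbhd.number_of_nodes(), nbhd.number_of_edges())
                    if d > fluff_threshold:
                        extra.add(w)
            members = members | extra
        cluster = score_cluster(members, net)
        clusters.append(
            ModuleCluster(
                nodes=cluster.nodes,
                n_edges=cluster.n_edges,
                density=cluster.density,
                score=cluster.score,
                seed_node=seed,
            )
        )
    return clusters


def filter_clusters(
    clusters: Iterable[ModuleCluster],
    score_cutoff: float = 4.0,
    strict: bool = True,
) -> list[ModuleCluster]:
    """Keep clusters scoring > cutoff (strict) or >= cutoff, sorted by
    descending score (ties: larger, then lexicographically first member)."""
    kept = [
        c
        for c in clusters
        if (c.score > score_cutoff if strict else c.score >= score_cutoff)
    ]
    return sorted(kept, key=lambda c: (-c.score, -len(c.nodes), sorted(c.nodes)))


def write_cluster_table(clusters: Iterable[ModuleCluster], path: str | Path) -> None:
    """TSV: cluster id, n_nodes, n_edges, score, semicolon-joined members."""
    lines = ["cluster\tn_nodes\tn_edges\tscore\tmembers"]
    for i, c in enumerate(clusters, start=1):
        lines.append(
            f"{i}\t{len(c.nodes)}\t{c.n_edges}\t{c.score:g}\t"
            + ";".join(sorted(c.nodes))
        )
    Path(path).write_text("\n".join(lines) + "\n")
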