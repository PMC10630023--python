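"""Undirected PPI network container: parsing, merging, and degree-distribution fit.

Networks are simple undirected graphs over canonical gene symbols.  Each edge
carries a set of provenance tags identifying the interaction source(s) it was
read from, so merged networks retain per-source attribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def make_edge(a: str, b: str) -> Edge:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Network:
    """Simple undirected graph of gene-symbol nodes with per-edge provenance.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, and ``query_nodes`` (the differentially expressed input proteins)
    is a subset of ``nodes``.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)
    edge_sources: dict[Edge, set[str]] = field(default_factory=dict)
    query_nodes: set[str] = field(default_factory=set)

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    def add_edge(self, a: str, b: str, source: str | None = None) -> bool:
        """Add an undirected edge; self-loops are rejected (returns False)."""
        if a == b:
            return False
        e = make_edge(a, b)
        self.nodes.add(a)
        self.nodes.add(b)
        new = e not in self.edges
        self.edges.add(e)
        tags = self.edge_sources.setdefault(e, set())
        if source is not None:
            tags.add(source)
        return new

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degrees(self) -> dict[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def subgraph(self, keep: Iterable[str]) -> "Network":
        keep = set(keep)
        sub = Network(nodes=keep & self.nodes)
        for e in self.edges:
            if e[0] in keep and e[1] in keep:
                sub.edges.add(e)
                sub.edge_sources[e] = set(self.edge_sources.get(e, set()))
        sub.query_nodes = self.query_nodes & sub.nodes
        return sub

    def connected_components(self) -> list[set[str]]:
        adj = self.adjacency()
        seen: set[str] = set()
        comps = []
        for start in sorted(self.nodes):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            comps.append(comp)
        return comps

    def copy(self) -> "Network":
        return Network(
            nodes=set(self.nodes),
            edges=set(self.edges),
            edge_sources={e: set(s) for e, s in self.edge_sources.items()},
            query_nodes=set(self.query_nodes),
        )

    def validate(self) -> None:
        """Assert the simple-graph invariants; raises ValueError on violation."""
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) has endpoint outside node set")
            if (b, a) in self.edges and a != b and (a, b) != make_edge(a, b):
                raise ValueError(f"non-canonical duplicate edge ({a!r}, {b!r})")
        if not self.query_nodes <= self.nodes:
            raise ValueError("query_nodes not a subset of nodes")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g, source: str | None = None) -> "Network":
        net = cls(nodes=set(map(str, g.nodes())))
        for a, b in g.edges():
            net.add_edge(str(a), str(b), source=source)
        return net


@dataclass(frozen=True)
class ScaleFreeFit:
    """Least-squares power-law fit to the empirical degree distribution.

    ``exponent`` is the slope of the log10(k) vs log10(P(k)) line and
    ``correlation`` the Pearson r of the fitted points.  The reported
    magnitude |correlation| is the statistic quoted by network-analysis
    tools as the goodness of the scale-free fit.
    """

    exponent: float
    correlation: float
    n_degree_bins: int

    @property
    def magnitude(self) -> float:
        return abs(self.correlation)


class UndefinedFitError(ValueError):
    """Raised when the degree distribution has too few usable bins."""


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column identifier map (from<TAB>to); '#' lines skipped."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        mapping[parts[0]] = parts[1]
    return mapping


def read_network(
    path: str | Path,
    dialect: str = "tsv",
    source_tag: str = "unknown",
    id_map: Mapping[str, str] | None = None,
) -> Network:
    """Read an edge list in TSV (node_a, node_b[, source[, score]]) or SIF
    (node_a, relation, node_b) dialect.

    Self-loops are dropped with a logged count; duplicate edges collapse.
    Identifiers are passed through ``id_map`` when given; unmapped ids are
    kept verbatim with a warning.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = Network()
    n_self_loops = 0
    unmapped: set[str] = set()

    def canon(name: str) -> str:
        if id_map is None:
            return name
        if name in id_map:
            return id_map[name]
        unmapped.add(name)
        return name

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and parts[:2] == ["node_a", "node_b"]:
            continue  # header written by write_network
        if dialect == "sif":
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: SIF line needs 3 fields, got {len(parts)}"
                )
            a, _, b = parts
        else:
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: TSV edge line needs >= 2 fields, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
        a, b = canon(a), canon(b)
        if a == b:
            n_self_loops += 1
            net.add_node(a)
            continue
        net.add_edge(a, b, source=source_tag)
    if n_self_loops:
        logger.info("dropped %d self-loop(s) reading %s", n_self_loops, path)
    if unmapped:
        logger.warning(
            "%d identifier(s) not in id_map kept verbatim: %s",
            len(unmapped),
            ", ".join(sorted(unmapped)[:10]),
        )
    return net


def write_network(net: Network, path: str | Path) -> None:
    """Write a canonical TSV edge list (node_a, node_b, comma-joined sources)."""
    lines = ["node_a\tnode_b\tsource"]
    for a, b in sorted(net.edges):
        tags = ",".join(sorted(net.edge_sources.get((a, b), set())))
        lines.append(f"{a}\t{b}\t{tags}")
    Path(path).write_text("\n".join(lines) + "\n")


def merge_networks(nets: Iterable[Network]) -> Network:
    """Union of node sets, edge sets, per-edge source tags and query sets."""
    nets = list(nets)
    if not nets:
        raise ValueError("merge_networks requires at least one network")
    merged = Network()
    for net in nets:
        merged.nodes |= net.nodes
        merged.query_nodes |= net.query_nodes
        for e in net.edges:
            merged.edges.add(e)
            merged.edge_sources.setdefault(e, set()).update(
                net.edge_sources.get(e, set())
            )
    return merged


def fit_power_law(degrees: Iterable[int]) -> ScaleFreeFit:
    """Fit log10 P(k) ~ log10 k over the positive-degree empirical distribution.

    Zero-count bins are omitted (only observed degrees form bins).  Requires
    at least 3 distinct positive degree values.
    """
    degs = np.asarray([d for d in degrees if d >= 1], dtype=float)
    if degs.size == 0:
        raise UndefinedFitError("no positive degrees")
    ks, counts = np.unique(degs, return_counts=True)
    if ks.size < 3:
        raise UndefinedFitError(
            f"need >= 3 distinct positive degree values, got {ks.size}"
        )
    pk = counts / counts.sum()
    res = stats.linregress(np.log10(ks), np.log10(pk))
    return ScaleFreeFit(
        exponent=float(res.slope),
        correlation=float(res.rvalue),
        n_degree_bins=int(ks.size),
    )


def scale_free_fit(net: Network) -> ScaleFreeFit:
    """Power-law fit of the network's degree distribution (degrees >= 1)."""
    return fit_power_law(net.degrees().values())


def network_summary(net: Network) -> dict:
    """JSON-serializable description: sizes, per-source edge counts, fit."""
    per_source: dict[str, int] = {}
    for tags in net.edge_sources.values():
        for t in tags:
            per_source[t] = per_source.get(t, 0) + 1
    summary: dict = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_query_nodes": len(net.query_nodes),
        "edges_per_source": dict(sorted(per_source.items())),
    }
    try:
        fit = scale_free_fit(net)
        summary["scale_free_fit"] = {
            "exponent": fit.exponent,
            "correlation": fit.correlation,
            "magnitude": fit.magnitude,
            "n_degree_bins": fit.n_degree_bins,
        }
    except UndefinedFitError:
        summary["scale_free_fit"] = None
    return summary
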