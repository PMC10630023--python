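"""Degree/betweenness centrality and hub-bottleneck selection.

Hubs are nodes whose degree reaches mean + multiplier x SD of the degree
distribution (sample SD by default, multiplier 2); bottlenecks are the top
fraction (default 10%) of nodes by betweenness centrality; hub-bottlenecks
are their intersection.  A cross-network consensus restricts the
intersection of several selections to the differentially expressed query
proteins.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import Network


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    degree: int
    betweenness: float


@dataclass
class SelectionResult:
    """Hubs, bottlenecks and their intersection for one network, plus the
    realized thresholds."""

    hubs: set[str] = field(default_factory=set)
    bottlenecks: set[str] = field(default_factory=set)
    hub_threshold: float | None = None
    bottleneck_fraction: float | None = None
    hub_bottlenecks_override: set[str] | None = None

    @property
    def hub_bottlenecks(self) -> set[str]:
        if self.hub_bottlenecks_override is not None:
            return set(self.hub_bottlenecks_override)
        return self.hubs & self.bottlenecks


def degree_centrality(net: Network) -> dict[str, int]:
    """Exact edge-count degree per node (sum of degrees = 2|E|)."""
    return net.degrees()


def betweenness_centrality(net: Network, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness via Brandes' dependency accumulation.

    Normalization is per connected component: within a component of size
    ``nc`` values are scaled by 2/((nc-1)(nc-2)) so that a node lying on
    every shortest path between all other component pairs scores 1.0.
    Components with fewer than 3 nodes contribute zeros by convention.
    """
    adj = net.adjacency()
    bc = dict.fromkeys(net.nodes, 0.0)
    for s in sorted(net.nodes):
        # single-source shortest paths (unweighted BFS)
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in adj}
        sigma = dict.fromkeys(adj, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in sorted(adj[v]):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(adj, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    for v in bc:
        bc[v] /= 2.0  # each unordered pair counted from both endpoints
    if normalized:
        for comp in net.connected_components():
            nc = len(comp)
            scale = 2.0 / ((nc - 1) * (nc - 2)) if nc >= 3 else 0.0
            for v in comp:
                bc[v] *= scale
    return bc


def hub_threshold(
    degrees: Mapping[str, int] | Sequence[int],
    sd_multiplier: float = 2.0,
    ddof: int = 1,
) -> float:
    """Mean + multiplier x SD of the degree multiset (sample SD by default)."""
    values = np.asarray(
        list(degrees.values()) if isinstance(degrees, Mapping) else list(degrees),
        dtype=float,
    )
    if values.size < 2:
        raise ValueError("hub threshold undefined for fewer than 2 nodes")
    return float(values.mean() + sd_multiplier * values.std(ddof=ddof))


def select_hubs(degrees: Mapping[str, int], threshold: float) -> set[str]:
    """Exactly the nodes with degree >= threshold."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return {v for v, d in degrees.items() if d >= threshold}


def select_bottlenecks(
    betweenness: Mapping[str, float],
    fraction: float = 0.10,
    degrees: Mapping[str, int] | None = None,
) -> set[str]:
    """The ceil(fraction x N) nodes of highest betweenness.

    Ties at the cut are broken by higher degree (when degrees are supplied),
    then lexicographic node id.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = len(betweenness)
    if n == 0:
        return set()
    k = math.ceil(fraction * n)
    ranked = sorted(
        betweenness,
        key=lambda v: (
            -betweenness[v],
            -(degrees.get(v, 0) if degrees else 0),
            v,
        ),
    )
    return set(ranked[:k])


def hub_bottlenecks(selection: SelectionResult) -> set[str]:
    """Intersection of the hub and bottleneck sets."""
    return selection.hub_bottlenecks


def select_network(
    net: Network,
    hub_sd_multiplier: float = 2.0,
    bottleneck_fraction: float = 0.10,
    hub_threshold_override: float | None = None,
) -> tuple[SelectionResult, list[CentralityRecord]]:
    """Run the full selection on a network: centralities, thresholds, sets."""
    deg = degree_centrality(net)
    bc = betweenness_centrality(net)
    threshold = (
        hub_threshold(deg, sd_multiplier=hub_sd_multiplier)
        if hub_threshold_override is None
        else float(hub_threshold_override)
    )
    selection = SelectionResult(
        hubs=select_hubs(deg, threshold),
        bottlenecks=select_bottlenecks(bc, bottleneck_fraction, degrees=deg),
        hub_threshold=threshold,
        bottleneck_fraction=bottleneck_fraction,
    )
    records = [
        CentralityRecord(node=v, degree=deg[v], betweenness=bc[v])
        for v in sorted(net.nodes, key=lambda v: (-deg[v], v))
    ]
    return selection, records


def consensus_candidates(
    selections: Iterable[SelectionResult], query_proteins: set[str]
) -> set[str]:
    """Intersection of all hub-bottleneck sets, restricted to the
    differentially expressed query proteins."""
    selections = list(selections)
    if not selections:
        raise ValueError("need at least one selection")
    consensus = set(selections[0].hub_bottlenecks)
    for sel in selections[1:]:
        consensus &= sel.hub_bottlenecks
    return consensus & set(query_proteins)


def read_centrality_table(path: str | Path) -> tuple[list[CentralityRecord], SelectionResult]:
    """Read a role-flagged centrality TSV (node, degree, betweenness, role).

    A node may appear once per role; ``role`` is ``hub`` or ``bottleneck``.
    The realized hub threshold is recovered as the minimum degree over the
    hub rows.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    records: dict[str, CentralityRecord] = {}
    hubs: set[str] = set()
    bottlenecks: set[str] = set()
    for row in df.itertuples(index=False):
        records[str(row.node)] = CentralityRecord(
            node=str(row.node), degree=int(row.degree), betweenness=float(row.betweenness)
        )
        if row.role == "hub":
            hubs.add(str(row.node))
        elif row.role == "bottleneck":
            bottlenecks.add(str(row.node))
        else:
            raise ValueError(f"unknown role {row.role!r}")
    threshold = float(min(records[v].degree for v in hubs)) if hubs else None
    selection = SelectionResult(
        hubs=hubs,
        bottlenecks=bottlenecks,
        hub_threshold=threshold,
        bottleneck_fraction=0.10,
    )
    return list(records.values()), selection


def write_selection_table(
    records: Iterable[CentralityRecord],
    selection: SelectionResult,
    path: str | Path,
) -> None:
    """TSV with one row per node: degree, betweenness and selection flags."""
    lines = ["node\tdegree\tbetweenness\thub\tbottleneck\thub_bottleneck"]
    hb = selection.hub_bottlenecks
    for r in records:
        lines.append(
            f"{r.node}\t{r.degree}\t{r.betweenness:.8f}"
            f"\t{int(r.node in selection.hubs)}"
            f"\t{int(r.node in selection.bottlenecks)}"
            f"\t{int(r.node in hb)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
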