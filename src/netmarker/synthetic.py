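"""Seeded generators for every input the pipeline consumes.

Spot tables use log-normal noise (densitometry is multiplicative), PPI
networks come from preferential attachment with an optional planted clique,
annotation collections carry one planted enriched term, and plasma
concentrations are zero-truncated Gaussians.  All generators are pure
functions of their arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationCollection
from .network import Network

GROUPS = ("respondent", "nonrespondent")


@dataclass(frozen=True)
class SyntheticSpotTruth:
    """Ground truth for one generated spot."""

    spot_id: str
    is_differential: bool
    planted_fc: float
    direction: str

    def __post_init__(self):
        if self.is_differential != (self.planted_fc != 1.0):
            raise ValueError("planted_fc must be 1 exactly when not differential")


@dataclass(frozen=True)
class SyntheticNetworkTruth:
    planted_module_nodes: frozenset[str] = frozenset()
    planted_hub_nodes: frozenset[str] = frozenset()


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Log-normal draws with arithmetic mean ``mean`` and coefficient of
    variation ``cv`` (degenerate at the mean when cv == 0)."""
    if cv == 0.0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def gen_spot_table(
    n_spots: int,
    n_differential: int,
    planted_fc: float,
    noise_cv: float,
    n_replicates: int = 3,
    seed: int = 0,
    base_intensity: float = 1000.0,
) -> tuple[pd.DataFrame, list[SyntheticSpotTruth]]:
    """Generate a long spot-intensity table with planted fold changes.

    The first ``n_differential`` spots get a between-group mean ratio of
    ``planted_fc`` (direction drawn per spot); the rest have ratio 1.
    Columns: spot_id, group, replicate, intensity.
    """
    if n_spots <= 0 or n_replicates < 2:
        raise ValueError("n_spots must be positive and n_replicates >= 2")
    if n_differential < 0 or n_differential > n_spots:
        raise ValueError("n_differential must be in [0, n_spots]")
    if planted_fc < 1.0:
        raise ValueError("planted_fc must be >= 1")
    if noise_cv < 0.0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    truths = []
    width = max(4, len(str(n_spots)))
    for i in range(n_spots):
        spot_id = f"S{i + 1:0{width}d}"
        differential = i < n_differential and planted_fc > 1.0
        # spread base abundances over an order of magnitude either way
        base = base_intensity * 10.0 ** rng.uniform(-1.0, 1.0)
        if differential:
            direction = "down" if rng.random() < 0.5 else "up"
            target = base / planted_fc if direction == "down" else base * planted_fc
        else:
            direction = "none"
            target = base
        means = {"respondent": base, "nonrespondent": target}
        for group in GROUPS:
            values = _lognormal_around(rng, means[group], noise_cv, n_replicates)
            for rep, val in enumerate(values, start=1):
                rows.append((spot_id, group, rep, float(val)))
        truths.append(
            SyntheticSpotTruth(
                spot_id=spot_id,
                is_differential=differential,
                planted_fc=planted_fc if differential else 1.0,
                direction=direction,
            )
        )
    table = pd.DataFrame(rows, columns=["spot_id", "group", "replicate", "intensity"])
    return table, truths


def gen_ppi_network(
    n_nodes: int,
    attach_m: int = 2,
    planted_clique: int = 0,
    seed: int = 0,
    n_planted_hubs: int = 0,
    hub_degree: int = 0,
) -> tuple[Network, SyntheticNetworkTruth]:
    """Preferential-attachment graph with an optional planted clique and
    optional planted high-degree nodes.

    The clique (size >= 3; 1 and 2 are rejected as meaningless modules) is
    wired onto randomly chosen existing nodes.  Planted hubs are existing
    non-clique nodes given ``hub_degree`` extra random attachments.
    """
    if attach_m < 1:
        raise ValueError("attach_m must be >= 1")
    if planted_clique in (1, 2):
        raise ValueError("a planted module needs at least 3 nodes")
    if planted_clique < 0 or planted_clique >= n_nodes:
        raise ValueError("need 0 <= planted_clique < n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_nodes)))
    label = {i: f"G{i + 1:0{width}d}" for i in g.nodes()}

    clique_idx = (
        sorted(rng.choice(n_nodes, size=planted_clique, replace=False).tolist())
        if planted_clique
        else []
    )
    for i, a in enumerate(clique_idx):
        for b in clique_idx[i + 1 :]:
            g.add_edge(a, b)

    hub_idx: list[int] = []
    if n_planted_hubs:
        candidates = [i for i in range(n_nodes) if i not in set(clique_idx)]
        hub_idx = sorted(
            rng.choice(candidates, size=n_planted_hubs, replace=False).tolist()
        )
        for h in hub_idx:
            others = [i for i in range(n_nodes) if i != h]
            targets = rng.choice(others, size=min(hub_degree, len(others)), replace=False)
            for t in targets.tolist():
                g.add_edge(h, t)

    net = Network()
    for i in g.nodes():
        net.add_node(label[i])
    for a, b in g.edges():
        net.add_edge(label[a], label[b], source="synthetic")
    net.validate()
    truth = SyntheticNetworkTruth(
        planted_module_nodes=frozenset(label[i] for i in clique_idx),
        planted_hub_nodes=frozenset(label[i] for i in hub_idx),
    )
    return net, truth


def gen_annotations(
    universe: set[str],
    n_terms: int,
    term_size: tuple[int, int] = (5, 20),
    enriched_term_genes: set[str] | None = None,
    seed: int = 0,
) -> AnnotationCollection:
    """Annotation collection over ``universe`` with one designated term equal
    to ``enriched_term_genes`` and the rest drawn uniformly."""
    if not universe:
        raise ValueError("universe must be non-empty")
    lo, hi = term_size
    if lo < 2:
        raise ValueError("term sizes must be >= 2")
    enriched = set(enriched_term_genes or set())
    if not enriched <= universe:
        raise ValueError("enriched_term_genes must be a subset of the universe")
    rng = np.random.default_rng(seed)
    ordered = sorted(universe)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    start = 1
    if enriched:
        terms["T0001"] = ("planted enriched term", frozenset(enriched))
        start = 2
    for i in range(start, n_terms + 1):
        size = int(rng.integers(lo, min(hi, len(ordered)) + 1))
        genes = rng.choice(len(ordered), size=size, replace=False)
        terms[f"T{i:04d}"] = (
            f"random term {i}",
            frozenset(ordered[j] for j in genes.tolist()),
        )
    return AnnotationCollection(terms=terms, background=frozenset(universe))


def gen_plasma_groups(
    group_means: tuple[float, float, float],
    group_sds: tuple[float, float, float],
    ns: tuple[int, int, int],
    seed: int = 0,
    labels: tuple[str, str, str] = ("respondent", "nonrespondent", "control"),
) -> pd.DataFrame:
    """Raw concentration table (columns group, value): Gaussian draws per
    group, truncated at zero by redrawing (not clipping)."""
    if any(s < 0 for s in group_sds):
        raise ValueError("SDs must be non-negative")
    if any(n < 2 for n in ns):
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd, n in zip(labels, group_means, group_sds, ns):
        values: list[float] = []
        while len(values) < n:
            draw = rng.normal(mean, sd, size=n - len(values))
            values.extend(float(v) for v in draw if v > 0)
        for v in values[:n]:
            rows.append((label, v))
    return pd.DataFrame(rows, columns=["group", "value"])
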