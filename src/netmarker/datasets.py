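"""Loaders for the bundled ITP drug-response demo dataset.

The package ships a small plain-text snapshot of a published chronic-ITP
plasma-proteomics analysis so the whole pipeline can run offline: the 19
differential 2-DE spot records, the merged-network centrality table with
hub/bottleneck flags, the HPRD-only hub-bottleneck list, an identifier map
(UniProt entry-name stems to gene symbols), the detected module table, and
the three-group plasma concentration summaries.

The spot table's source reports only that every spot passed p < 0.05; the
``p_value`` column therefore carries the documented upper-bound placeholder
0.049, not a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .centrality import CentralityRecord, SelectionResult, read_centrality_table
from .network import read_id_map
from .spots import SpotRecord, read_spot_annotations
from .validation import GroupSummary, read_summary_table


def _path(name: str):
    return resources.files("netmarker.data") / name


@dataclass(frozen=True)
class ModuleTableRow:
    """One row of the bundled module table (counts and score as printed)."""

    cluster: int
    n_nodes: int
    n_edges: int
    score: float
    input_proteins: tuple[str, ...]
    members: tuple[str, ...]


def load_demo_spots() -> list[SpotRecord]:
    """The 19 differential spot records (gene symbol, fold change, direction)."""
    with resources.as_file(_path("itp_spots.csv")) as p:
        return read_spot_annotations(p)


def load_demo_id_map() -> dict[str, str]:
    """UniProt entry-name stem -> gene symbol map for the demo proteins."""
    with resources.as_file(_path("itp_id_map.tsv")) as p:
        return read_id_map(p)


def load_demo_centrality() -> tuple[list[CentralityRecord], SelectionResult]:
    """Merged-network centrality rows plus the flagged hub/bottleneck sets."""
    with resources.as_file(_path("itp_merged_centrality.tsv")) as p:
        return read_centrality_table(p)


def load_demo_hprd_hub_bottlenecks(mapped: bool = True) -> SelectionResult:
    """Hub-bottlenecks of the HPRD-only network, as a selection carrying only
    that set; identifiers are mapped to gene symbols unless ``mapped=False``."""
    names = [
        line.strip()
        for line in _path("itp_hprd_hub_bottlenecks.txt").read_text().splitlines()
        if line.strip()
    ]
    if mapped:
        id_map = load_demo_id_map()
        names = [id_map.get(n, n) for n in names]
    return SelectionResult(hub_bottlenecks_override=set(names))


def load_demo_modules() -> list[ModuleTableRow]:
    """The three detected modules with their printed sizes and scores."""
    df = pd.read_csv(_path("itp_modules.tsv"), sep="\t")
    return [
        ModuleTableRow(
            cluster=int(row.cluster),
            n_nodes=int(row.n_nodes),
            n_edges=int(row.n_edges),
            score=float(row.score),
            input_proteins=tuple(str(row.input_proteins).split(";")),
            members=tuple(str(row.members).split(";")),
        )
        for row in df.itertuples(index=False)
    ]


def load_demo_plasma_summaries() -> dict[str, list[GroupSummary]]:
    """Per-protein (mean, SD, n) summaries for the three ELISA groups."""
    with resources.as_file(_path("itp_plasma_summary.csv")) as p:
        return read_summary_table(p)
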