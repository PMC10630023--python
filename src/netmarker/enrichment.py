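"""Over-representation analysis against a GMT annotation collection.

The statistic is the one-sided hypergeometric tail (Fisher exact), or its
conservative variant computed with the overlap reduced by one (the score
DAVID reports); the background is the union of genes in the collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationCollection:
    """Term id -> (description, gene set), plus the background universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self):
        for term, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            if not genes <= self.background:
                raise ValueError(f"term {term!r} has genes outside the background")

    @classmethod
    def from_gene_sets(cls, gene_sets: dict[str, Iterable[str]]) -> "AnnotationCollection":
        terms = {
            t: (t, frozenset(genes)) for t, genes in gene_sets.items()
        }
        background = frozenset().union(*(g for _, g in terms.values()))
        return cls(terms=terms, background=background)


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    description: str
    count: int
    p_value: float
    genes: tuple[str, ...]


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file (term, description, genes...)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        terms[parts[0]] = (parts[1], frozenset(parts[2:]))
    background = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    return AnnotationCollection(terms=terms, background=background)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    lines = []
    for term in collection.terms:
        desc, genes = collection.terms[term]
        lines.append("\t".join([term, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_tail(overlap: int, background: int, term_size: int, query_size: int) -> float:
    """P(X >= overlap) for X hypergeometric(background, term_size, query_size)."""
    if overlap <= 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, background, term_size, query_size))


def enrich(
    query: Iterable[str],
    collection: AnnotationCollection,
    mode: str = "ease",
    min_count: int = 2,
) -> list[EnrichmentRecord]:
    """One record per term with overlap >= min_count, sorted ascending by p.

    ``fisher`` uses the plain one-sided hypergeometric tail; ``ease`` the
    same tail with the overlap reduced by one (more conservative).
    """
    if mode not in ("fisher", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    query = set(query) & collection.background
    if not query:
        raise ValueError("query disjoint from collection background")
    n_bg = len(collection.background)
    n_query = len(query)
    records = []
    for term, (desc, genes) in collection.terms.items():
        overlap_genes = tuple(sorted(query & genes))
        k = len(overlap_genes)
        if k < min_count:
            continue
        effective = k if mode == "fisher" else k - 1
        p = hypergeom_tail(effective, n_bg, len(genes), n_query)
        records.append(
            EnrichmentRecord(
                term=term, description=desc, count=k, p_value=p, genes=overlap_genes
            )
        )
    records.sort(key=lambda r: (r.p_value, r.term))
    return records


def significance_filter(
    records: list[EnrichmentRecord], alpha: float = 0.05, adjust: str = "none"
) -> list[EnrichmentRecord]:
    """Keep records with p < alpha (or BH-adjusted q < alpha), order preserved."""
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if not records:
        return []
    if adjust == "none":
        return [r for r in records if r.p_value < alpha]
    reject, _, _, _ = multipletests(
        [r.p_value for r in records], alpha=alpha, method="fdr_bh"
    )
    return [r for r, keep in zip(records, reject) if keep]


def write_enrichment_table(records: Iterable[EnrichmentRecord], path: str | Path) -> None:
    lines = ["term\tdescription\tcount\tp_value\tgenes"]
    for r in records:
        lines.append(
            f"{r.term}\t{r.description}\t{r.count}\t{r.p_value:.6g}\t"
            + ";".join(r.genes)
        )
    Path(path).write_text("\n".join(lines) + "\n")
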