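"""Differential 2-DE spot analysis.

Replicate spot-intensity tables are reduced to per-spot records carrying a
fold change (always reported >= 1, with an explicit direction for the
nonrespondent condition) and a one-way ANOVA p-value; records are then
filtered on the fold-change/significance cutoffs, tallied by direction, and
de-duplicated to unique proteins.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DIRECTIONS = ("down", "up", "none")


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA outcome, with the within-group mean
    square exposed for downstream multiple-comparison procedures."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    mse: float


@dataclass(frozen=True)
class SpotRecord:
    """One 2-DE spot: identity, fold change (ratio >= 1 plus direction in the
    nonrespondent condition) and significance."""

    spot_id: str
    fold_change: float
    direction: str
    p_value: float | None = None
    gene_symbol: str | None = None
    mascot_score: float | None = None

    def __post_init__(self):
        if self.fold_change < 1:
            raise ValueError(
                f"fold_change must be >= 1 (direction carries the sign); "
                f"got {self.fold_change}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def spot_anova(groups: Sequence[Sequence[float]], log_transform: bool = True) -> AnovaResult:
    """Classical one-way ANOVA across >= 2 replicate groups.

    Intensities are log-transformed by default (densitometry noise is
    multiplicative); disable with ``log_transform=False``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            raise ValueError("every group needs at least two values")
        if log_transform:
            if np.any(a <= 0):
                raise ValueError("non-positive intensity with log transform enabled")
            a = np.log(a)
        arrays.append(a)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    mse = ss_within / df_within
    if mse == 0.0:
        f = 0.0 if ss_between == 0.0 else math.inf
    else:
        f = (ss_between / df_between) / mse
    p = float(stats.f.sf(f, df_between, df_within)) if math.isfinite(f) else 0.0
    return AnovaResult(
        f_stat=float(f),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        mse=float(mse),
    )


def fold_change(reference_mean: float, target_mean: float) -> tuple[float, str]:
    """Fold change between the reference (respondent) and target
    (nonrespondent) group means, as a ratio >= 1 plus the direction of the
    target group relative to the reference.
    """
    if reference_mean <= 0 or target_mean <= 0:
        raise ValueError("group means must be positive")
    if target_mean == reference_mean:
        return 1.0, "none"
    fc = max(reference_mean / target_mean, target_mean / reference_mean)
    direction = "down" if target_mean < reference_mean else "up"
    return float(fc), direction


def normalize_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """Total-intensity scaling per gel (one gel = one group x replicate pair).

    Each intensity is rescaled so every gel has the same total, equal to the
    mean per-gel total; relative spot abundances within a gel are preserved.
    """
    out = table.copy()
    totals = out.groupby(["group", "replicate"])["intensity"].transform("sum")
    mean_total = out.groupby(["group", "replicate"])["intensity"].sum().mean()
    out["intensity"] = out["intensity"] / totals * mean_total
    return out


def analyze_spot_table(
    table: pd.DataFrame,
    reference_group: str = "respondent",
    target_group: str = "nonrespondent",
    log_transform: bool = True,
    normalize: bool = True,
) -> list[SpotRecord]:
    """Turn a long spot-intensity table (spot_id, group, replicate, intensity)
    into per-spot records with fold change, direction and ANOVA p-value."""
    required = {"spot_id", "group", "replicate", "intensity"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if normalize:
        table = normalize_intensities(table)
    records = []
    for spot_id, sub in table.groupby("spot_id", sort=True):
        ref = sub.loc[sub["group"] == reference_group, "intensity"].to_numpy()
        tgt = sub.loc[sub["group"] == target_group, "intensity"].to_numpy()
        if ref.size < 2 or tgt.size < 2:
            raise ValueError(f"spot {spot_id!r}: need >= 2 replicates per group")
        anova = spot_anova([ref, tgt], log_transform=log_transform)
        fc, direction = fold_change(float(ref.mean()), float(tgt.mean()))
        records.append(
            SpotRecord(
                spot_id=str(spot_id),
                fold_change=fc,
                direction=direction,
                p_value=anova.p_value,
            )
        )
    return records


def filter_spots(
    records: Iterable[SpotRecord], fc_min: float = 1.5, alpha: float = 0.05
) -> list[SpotRecord]:
    """Keep records with fold_change >= fc_min AND p_value < alpha (strict),
    preserving input order."""
    kept = []
    for r in records:
        if r.p_value is None:
            raise ValueError(f"record {r.spot_id!r} has no p_value")
        if r.fold_change >= fc_min and r.p_value < alpha:
            kept.append(r)
    return kept


def tabulate_directions(records: Iterable[SpotRecord]) -> dict[str, int]:
    """Exact per-direction counts over records with an up/down direction."""
    counts = Counter(r.direction for r in records)
    return {"down": counts.get("down", 0), "up": counts.get("up", 0)}


def dedupe_proteins(records: Iterable[SpotRecord]) -> list[str]:
    """Unique gene symbols in first-seen order; records without a symbol are
    skipped with a warning."""
    seen: set[str] = set()
    out: list[str] = []
    for r in records:
        if not r.gene_symbol:
            logger.warning("spot %s has no gene symbol; skipped", r.spot_id)
            continue
        if r.gene_symbol not in seen:
            seen.add(r.gene_symbol)
            out.append(r.gene_symbol)
    return out


def read_spot_annotations(path: str | Path) -> list[SpotRecord]:
    """Read an annotation CSV with columns spot_id, mascot_id, gene, score,
    direction, fold_change[, p_value]."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        p = getattr(row, "p_value", None)
        records.append(
            SpotRecord(
                spot_id=str(row.spot_id),
                fold_change=float(row.fold_change),
                direction=str(row.direction),
                p_value=None if p is None or pd.isna(p) else float(p),
                gene_symbol=str(row.gene) if pd.notna(row.gene) else None,
                mascot_score=float(row.score) if pd.notna(row.score) else None,
            )
        )
    return records


def write_spot_records(records: Iterable[SpotRecord], path: str | Path) -> None:
    """Write retained spots as TSV."""
    lines = ["spot_id\tgene\tfold_change\tdirection\tp_value\tmascot_score"]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.spot_id,
                    r.gene_symbol or "",
                    f"{r.fold_change:g}",
                    r.direction,
                    "" if r.p_value is None else f"{r.p_value:g}",
                    "" if r.mascot_score is None else f"{r.mascot_score:g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
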