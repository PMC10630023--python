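"""Three-group concentration validation: one-way ANOVA and Tukey HSD.

Both procedures run either from raw per-sample values or from printed
summary statistics (mean, SD, n per group); the two routes agree exactly
when the summaries are exact.  Tukey simultaneous confidence intervals use
studentized-range quantiles computed numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spots import AnovaResult

P_CATEGORIES = (0.0001, 0.001, 0.01, 0.05)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary: label, mean, SD and sample size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class TukeyComparison:
    """One pairwise contrast with its simultaneous CI and significance label."""

    pair: tuple[str, str]
    diff: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    p_category: str


def summarize(label: str, values: Sequence[float]) -> GroupSummary:
    a = np.asarray(values, dtype=float)
    return GroupSummary(label=label, mean=float(a.mean()), sd=float(a.std(ddof=1)), n=a.size)


def anova_from_summary(summaries: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from (mean, SD, n) per group.

    MSE pools the within-group variances; the between-group sum of squares
    comes from the group means and sizes.  Identical to the raw-data ANOVA
    when summaries are exact.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df_between = len(summaries) - 1
    df_within = int(n_total) - len(summaries)
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


def anova_from_raw(groups: dict[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from raw per-group values."""
    return anova_from_summary([summarize(label, v) for label, v in groups.items()])


@lru_cache(maxsize=512)
def studentized_range_quantile(alpha: float, k: int, df: int) -> float:
    """Upper-alpha quantile of the studentized range for k groups, df error.

    Cached: quantile evaluation is numerically expensive and simulation
    loops reuse the same (alpha, k, df) triple.
    """
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(
    summaries: Sequence[GroupSummary], alpha: float = 0.05, compute_p: bool = True
) -> list[TukeyComparison]:
    """All-pairs Tukey HSD from group summaries.

    For a pair (i, j): diff = mean_i - mean_j, standard error
    sqrt(MSE/2 * (1/n_i + 1/n_j)), CI half-width q(alpha, k, df) x SE, and
    p-value from the studentized-range survival function.  The significance
    category is the strictest conventional level at which zero leaves the
    CI.  With ``compute_p=False`` the (slow) survival-function evaluation is
    skipped and ``p_value`` is reported as nan; significance flags and
    categories are unaffected, since they derive from cached quantiles.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    anova = anova_from_summary(summaries)
    k = len(summaries)
    df = anova.df_within
    q_crit = studentized_range_quantile(alpha, k, df)
    out = []
    for a, b in combinations(summaries, 2):
        diff = a.mean - b.mean
        se = math.sqrt(anova.mse / 2.0 * (1.0 / a.n + 1.0 / b.n))
        if se == 0.0:
            q_obs = 0.0 if diff == 0.0 else math.inf
            half = 0.0
        else:
            q_obs = abs(diff) / se
            half = q_crit * se
        category = "ns"
        for level in sorted(P_CATEGORIES):
            if q_obs > studentized_range_quantile(level, k, df):
                category = f"<{level:g}"
                break
        if compute_p:
            if math.isinf(q_obs):
                p = 0.0
            else:
                p = float(stats.studentized_range.sf(q_obs, k, df))
        else:
            p = math.nan
        out.append(
            TukeyComparison(
                pair=(a.label, b.label),
                diff=diff,
                ci_low=diff - half,
                ci_high=diff + half,
                p_value=p,
                significant=q_obs > q_crit,
                p_category=category,
            )
        )
    return out


def tukey_hsd_from_raw(
    groups: dict[str, Sequence[float]], alpha: float = 0.05, compute_p: bool = True
) -> list[TukeyComparison]:
    return tukey_hsd(
        [summarize(label, v) for label, v in groups.items()],
        alpha=alpha,
        compute_p=compute_p,
    )


def read_summary_table(path: str | Path) -> dict[str, list[GroupSummary]]:
    """Read a summary CSV (protein, group, mean, sd, n) into per-protein
    summary lists; a file without a protein column yields a single entry
    keyed ''."""
    df = pd.read_csv(path)
    key = "protein" if "protein" in df.columns else None
    out: dict[str, list[GroupSummary]] = {}
    for row in df.itertuples(index=False):
        label = str(getattr(row, key)) if key else ""
        out.setdefault(label, []).append(
            GroupSummary(
                label=str(row.group),
                mean=float(row.mean),
                sd=float(row.sd),
                n=int(row.n),
            )
        )
    return out


def read_raw_table(path: str | Path) -> dict[str, dict[str, list[float]]]:
    """Read a raw CSV (group, value[, protein]) into per-protein group dicts."""
    df = pd.read_csv(path)
    key = "protein" if "protein" in df.columns else None
    out: dict[str, dict[str, list[float]]] = {}
    for row in df.itertuples(index=False):
        label = str(getattr(row, key)) if key else ""
        out.setdefault(label, {}).setdefault(str(row.group), []).append(float(row.value))
    return out


def write_comparison_table(
    comparisons: Iterable[TukeyComparison], path: str | Path, label: str = ""
) -> None:
    lines = ["protein\tgroup_a\tgroup_b\tdiff\tci_low\tci_high\tp_value\tsignificance"]
    for c in comparisons:
        lines.append(
            f"{label}\t{c.pair[0]}\t{c.pair[1]}\t{c.diff:.6g}\t{c.ci_low:.6g}"
            f"\t{c.ci_high:.6g}\t{c.p_value:.6g}\t{c.p_category}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
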