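"""End-to-end orchestration: spots -> network -> select -> modules ->
enrich -> validate, driven by a flat YAML config.

Stages with no configured inputs fall back to the bundled demo dataset when
``use_demo_fixtures`` is on (the default), so the default configuration
reproduces the bundled worked example offline.  A failing stage aborts with
a stage-tagged error after recording a partial report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import datasets
from .centrality import (
    SelectionResult,
    consensus_candidates,
    read_centrality_table,
    select_network,
)
from .enrichment import enrich, read_gmt, significance_filter
from .mcode import filter_clusters, find_complexes
from .network import merge_networks, network_summary, read_id_map, read_network
from .spots import (
    analyze_spot_table,
    dedupe_proteins,
    filter_spots,
    read_spot_annotations,
    tabulate_directions,
)
from .validation import anova_from_summary, read_raw_table, read_summary_table, summarize, tukey_hsd

logger = logging.getLogger(__name__)

STAGES = ("spots", "network", "select", "modules", "enrich", "validate")

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "use_demo_fixtures": True,
    "stages": list(STAGES),
    "spots": {"annotation_csv": None, "intensity_csv": None, "fc_min": 1.5, "alpha": 0.05},
    "network": {"edge_lists": [], "id_map": None},
    "select": {
        "hub_sd_multiplier": 2.0,
        "bottleneck_fraction": 0.10,
        "hub_threshold_override": None,
        "centrality_table": None,
        "extra_hub_bottleneck_lists": [],
    },
    "modules": {"score_cutoff": 4.0, "strict": True},
    "enrich": {"gmt": None, "alpha": 0.05, "mode": "ease", "min_count": 2},
    "validate": {"summary_csv": None, "raw_csv": None, "alpha": 0.05},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (flat YAML, defaults filled in)."""

    settings: dict[str, Any] = field(default_factory=lambda: json.loads(json.dumps(DEFAULTS)))

    def __post_init__(self):
        self.settings = _deep_merge(DEFAULTS, self.settings)
        sel = self.settings["select"]
        if not (0.0 < sel["bottleneck_fraction"] <= 1.0):
            raise ValueError("bottleneck_fraction must be in (0, 1]")
        if sel["hub_sd_multiplier"] < 0:
            raise ValueError("hub_sd_multiplier must be >= 0")
        for alpha_key in (("spots", "alpha"), ("enrich", "alpha"), ("validate", "alpha")):
            a = self.settings[alpha_key[0]][alpha_key[1]]
            if not (0.0 < a <= 1.0):
                raise ValueError(f"{alpha_key[0]}.{alpha_key[1]} must be in (0, 1]")
        unknown = set(self.settings["stages"]) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        return cls(settings=loaded)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.settings, sort_keys=True))

    def hash(self) -> str:
        canon = json.dumps(self.settings, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def __getitem__(self, key: str) -> Any:
        return self.settings[key]


@dataclass
class PipelineReport:
    """Per-stage summaries plus provenance (config hash, seed)."""

    stages: dict[str, dict] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineReport":
        return cls(stages=d["stages"], provenance=d["provenance"])


def _demo_or(path, use_demo: bool, loader):
    """Return user-supplied input when given, demo data when allowed, else None."""
    if path is not None:
        return path, False
    if use_demo:
        return loader, True
    return None, False


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute the enabled stages in order.

    The retained differential proteins become the network query set and the
    consensus hub-bottlenecks feed the validation summary.  Raises
    ``StageError`` on the first failing stage (after writing a partial
    report when ``out_dir`` is given).
    """
    report = PipelineReport(
        provenance={"config_hash": config.hash(), "seed": config["seed"]}
    )
    state: dict[str, Any] = {"query_proteins": set(), "network": None, "selection": None}
    enabled = config["stages"]
    use_demo = config["use_demo_fixtures"]

    runners = {
        "spots": _run_spots,
        "network": _run_network,
        "select": _run_select,
        "modules": _run_modules,
        "enrich": _run_enrich,
        "validate": _run_validate,
    }
    for stage in STAGES:
        if stage not in enabled:
            report.stages[stage] = {"status": "disabled"}
            continue
        try:
            summary = runners[stage](config, state, use_demo)
        except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
            report.stages[stage] = {"status": "failed", "error": str(exc)}
            if out_dir is not None:
                write_report(report, out_dir)
            raise StageError(stage, exc) from exc
        report.stages[stage] = summary
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _run_spots(config: PipelineConfig, state: dict, use_demo: bool) -> dict:
    cfg = config["spots"]
    if cfg["intensity_csv"] is not None:
        table = pd.read_csv(cfg["intensity_csv"])
        records = analyze_spot_table(table)
    elif cfg["annotation_csv"] is not None:
        records = read_spot_annotations(cfg["annotation_csv"])
    elif use_demo:
        records = datasets.load_demo_spots()
    else:
        return {"status": "skipped", "reason": "no spot input configured"}
    retained = filter_spots(records, fc_min=cfg["fc_min"], alpha=cfg["alpha"])
    directions = tabulate_directions(retained)
    proteins = dedupe_proteins(retained)
    state["query_proteins"] = set(proteins)
    return {
        "status": "ok",
        "n_input_spots": len(records),
        "n_retained_spots": len(retained),
        "directions": directions,
        "n_unique_proteins": len(proteins),
        "proteins": proteins,
        "fc_min": cfg["fc_min"],
        "alpha": cfg["alpha"],
    }


def _run_network(config: PipelineConfig, state: dict, use_demo: bool) -> dict:
    cfg = config["network"]
    if not cfg["edge_lists"]:
        return {"status": "skipped", "reason": "no edge lists configured"}
    id_map = read_id_map(cfg["id_map"]) if cfg["id_map"] else None
    nets = []
    per_source = {}
    for entry in cfg["edge_lists"]:
        net = read_network(
            entry["path"],
            dialect=entry.get("dialect", "tsv"),
            source_tag=entry.get("source", Path(entry["path"]).stem),
            id_map=id_map,
        )
        net.query_nodes = state["query_proteins"] & net.nodes
        per_source[entry.get("source", Path(entry["path"]).stem)] = network_summary(net)
        nets.append(net)
    merged = merge_networks(nets)
    merged.query_nodes = state["query_proteins"] & merged.nodes
    state["network"] = merged
    state["component_networks"] = nets
    return {"status": "ok", "sources": per_source, "merged": network_summary(merged)}


def _run_select(config: PipelineConfig, state: dict, use_demo: bool) -> dict:
    cfg = config["select"]
    if state["network"] is not None:
        selection, records = select_network(
            state["network"],
            hub_sd_multiplier=cfg["hub_sd_multiplier"],
            bottleneck_fraction=cfg["bottleneck_fraction"],
            hub_threshold_override=cfg["hub_threshold_override"],
        )
    elif cfg["centrality_table"] is not None:
        records, selection = read_centrality_table(cfg["centrality_table"])
    elif use_demo:
        records, selection = datasets.load_demo_centrality()
    else:
        return {"status": "skipped", "reason": "no network or centrality table"}

    selections = [selection]
    for path in cfg["extra_hub_bottleneck_lists"]:
        names = {
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
        selections.append(SelectionResult(hub_bottlenecks_override=names))
    if use_demo and state["network"] is None and not cfg["extra_hub_bottleneck_lists"]:
        selections.append(datasets.load_demo_hprd_hub_bottlenecks(mapped=True))

    query = state["query_proteins"]
    consensus = (
        consensus_candidates(selections, query) if query else set()
    )
    state["selection"] = selection
    state["consensus"] = consensus
    state["centrality_records"] = records
    return {
        "status": "ok",
        "hub_threshold": selection.hub_threshold,
        "bottleneck_fraction": selection.bottleneck_fraction,
        "hubs": sorted(selection.hubs),
        "bottlenecks": sorted(selection.bottlenecks),
        "hub_bottlenecks": sorted(selection.hub_bottlenecks),
        "n_selections_intersected": len(selections),
        "consensus_candidates": sorted(consensus),
    }


def _run_modules(config: PipelineConfig, state: dict, use_demo: bool) -> dict:
    cfg = config["modules"]
    if state["network"] is not None:
        clusters = find_complexes(state["network"])
        kept = filter_clusters(clusters, score_cutoff=cfg["score_cutoff"], strict=cfg["strict"])
        rows = [
            {
                "n_nodes": len(c.nodes),
                "n_edges": c.n_edges,
                "score": c.score,
                "members": sorted(c.nodes),
            }
            for c in kept
        ]
        n_detected = len(clusters)
    elif use_demo:
        table = datasets.load_demo_modules()
        kept_rows = [
            r
            for r in table
            if (r.score > cfg["score_cutoff"] if cfg["strict"] else r.score >= cfg["score_cutoff"])
        ]
        rows = [
            {
                "n_nodes": r.n_nodes,
                "n_edges": r.n_edges,
                "score": r.score,
                "members": list(r.members),
            }
            for r in kept_rows
        ]
        n_detected = len(table)
    else:
        return {"status": "skipped", "reason": "no network or module table"}
    return {
        "status": "ok",
        "score_cutoff": cfg["score_cutoff"],
        "strict": cfg["strict"],
        "n_detected": n_detected,
        "n_kept": len(rows),
        "modules": rows,
    }


def _run_enrich(config: PipelineConfig, state: dict, use_demo: bool) -> dict:
    cfg = config["enrich"]
    if cfg["gmt"] is None:
        return {"status": "skipped", "reason": "no annotation collection configured"}
    if not state["query_proteins"]:
        return {"status": "skipped", "reason": "no query proteins available"}
    collection = read_gmt(cfg["gmt"])
    records = enrich(
        state["query_proteins"], collection, mode=cfg["mode"], min_count=cfg["min_count"]
    )
    significant = significance_filter(records, alpha=cfg["alpha"])
    return {
        "status": "ok",
        "mode": cfg["mode"],
        "alpha": cfg["alpha"],
        "n_terms_tested": len(records),
        "n_significant": len(significant),
        "top_terms": [
            {"term": r.term, "count": r.count, "p_value": r.p_value, "genes": list(r.genes)}
            for r in significant[:20]
        ],
    }


def _run_validate(config: PipelineConfig, state: dict, use_demo: bool) -> dict:
    cfg = config["validate"]
    alpha = cfg["alpha"]
    if cfg["raw_csv"] is not None:
        raw = read_raw_table(cfg["raw_csv"])
        per_protein = {
            name: [summarize(g, v) for g, v in groups.items()] for name, groups in raw.items()
        }
    elif cfg["summary_csv"] is not None:
        per_protein = read_summary_table(cfg["summary_csv"])
    elif use_demo:
        per_protein = datasets.load_demo_plasma_summaries()
    else:
        return {"status": "skipped", "reason": "no concentration data configured"}
    results = {}
    for name, summaries in per_protein.items():
        anova = anova_from_summary(summaries)
        comparisons = tukey_hsd(summaries, alpha=alpha)
        results[name] = {
            "anova": {"f": anova.f_stat, "p": anova.p_value, "mse": anova.mse,
                      "df": [anova.df_between, anova.df_within]},
            "comparisons": [
                {
                    "pair": list(c.pair),
                    "diff": c.diff,
                    "ci": [c.ci_low, c.ci_high],
                    "p_value": c.p_value,
                    "significance": c.p_category,
                }
                for c in comparisons
            ],
        }
    return {"status": "ok", "alpha": alpha, "proteins": results}


def write_report(report: PipelineReport, out_dir: str | Path, format: str = "json") -> list[Path]:
    """Write the report as round-trippable JSON, optionally plus a TSV bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    written.append(json_path)
    if format == "tsv-bundle":
        written.extend(_write_tsv_bundle(report, out_dir))
    elif format != "json":
        raise ValueError(f"unknown report format {format!r}")
    return written


def read_report(out_dir: str | Path) -> PipelineReport:
    return PipelineReport.from_dict(json.loads((Path(out_dir) / "report.json").read_text()))


def _write_tsv_bundle(report: PipelineReport, out_dir: Path) -> list[Path]:
    written = []
    select = report.stages.get("select", {})
    if select.get("status") == "ok":
        path = out_dir / "selection.tsv"
        lines = ["node\thub\tbottleneck\thub_bottleneck"]
        nodes = sorted(set(select["hubs"]) | set(select["bottlenecks"]))
        hb = set(select["hub_bottlenecks"])
        for v in nodes:
            lines.append(
                f"{v}\t{int(v in set(select['hubs']))}"
                f"\t{int(v in set(select['bottlenecks']))}\t{int(v in hb)}"
            )
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    modules = report.stages.get("modules", {})
    if modules.get("status") == "ok":
        path = out_dir / "modules.tsv"
        lines = ["module\tn_nodes\tn_edges\tscore\tmembers"]
        for i, m in enumerate(modules["modules"], start=1):
            lines.append(
                f"{i}\t{m['n_nodes']}\t{m['n_edges']}\t{m['score']:g}\t"
                + ";".join(m["members"])
            )
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    validate = report.stages.get("validate", {})
    if validate.get("status") == "ok":
        path = out_dir / "validation.tsv"
        lines = ["protein\tgroup_a\tgroup_b\tdiff\tci_low\tci_high\tp_value\tsignificance"]
        for name, res in validate["proteins"].items():
            for c in res["comparisons"]:
                lines.append(
                    f"{name}\t{c['pair'][0]}\t{c['pair'][1]}\t{c['diff']:.6g}"
                    f"\t{c['ci'][0]:.6g}\t{c['ci'][1]:.6g}\t{c['p_value']:.6g}"
                    f"\t{c['significance']}"
                )
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
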