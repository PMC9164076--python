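"""End-to-end orchestration from a single YAML config.

A run executes, in order: compound screening → two-stage target overlap →
pathway enrichment and key-pathway selection → tripartite network
construction with degree analysis → PPI double-filter hub isolation →
docking-score triage.  Every stage writes its artifact files under the
configured output directory, and the machine-readable run report echoes the
config, records per-stage summaries, and references every artifact.

Inputs come either from files (``inputs:`` block) or from the synthetic
generator (``synthetic:`` block); exactly one must be present.  All
thresholds are surfaced in ``params:`` with the study's defaults (TPSA 140,
alpha 0.05, filter fraction 0.30, docking threshold −6.0).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .chem import read_compound_table, screen
from .docking import best_binder, classify_binders, parse_scores
from .enrichment import bubble_data, enrich, key_pathway
from .errors import ConfigError, PipelineStageError
from .graphs import build_pta, degree_table, isolate_hub, layer_degree_summary
from .ingest import (
    read_edge_list,
    read_gmt,
    read_prediction_table,
    read_symbol_list,
    write_graphml,
    write_symbol_list,
)
from .overlap import TargetSet, two_stage_overlap, write_venn_json
from .simulate import SynthConfig, write_study

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "tpsa_threshold": 140.0,
    "alpha": 0.05,
    "fraction": 0.30,
    "docking_threshold": -6.0,
    "background_size": 20000,
    "min_confidence": 0.0,
    "lipinski_bounds": {"mw": 500.0, "hba": 10, "hbd": 5, "mlogp": 4.15},
}

_INPUT_KEYS = (
    "compounds",
    "predictions_a",
    "predictions_b",
    "disease_targets",
    "pathways",
    "ppi_edges",
    "docking_scores",
)

_TOP_KEYS = {"seed", "output_dir", "inputs", "synthetic", "params"}


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    try:
        with open(path, encoding="utf-8") as handle:
            parsed = yaml.safe_load(handle)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse YAML: {exc}") from exc
    if not isinstance(parsed, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(parsed).__name__}")
    return parsed


def validate_config(config: str | Path | dict) -> list[str]:
    """Collect every schema problem at once; empty list means valid."""
    cfg = load_config(config)
    problems: list[str] = []
    for key in cfg:
        if key not in _TOP_KEYS:
            problems.append(f"unknown top-level key '{key}'")
    has_inputs = "inputs" in cfg
    has_synth = "synthetic" in cfg
    if has_inputs == has_synth:
        problems.append("config needs exactly one of 'inputs' or 'synthetic'")
    if has_inputs and isinstance(cfg.get("inputs"), dict):
        for key in _INPUT_KEYS:
            if key not in cfg["inputs"]:
                problems.append(f"inputs: missing entry '{key}'")
            elif not Path(cfg["inputs"][key]).exists():
                problems.append(f"inputs.{key}: file not found: {cfg['inputs'][key]}")
    elif has_inputs:
        problems.append("'inputs' must be a mapping of input names to paths")
    if has_synth and not isinstance(cfg.get("synthetic"), (dict, type(None))):
        problems.append("'synthetic' must be a mapping of generator parameters (or empty)")
    params = cfg.get("params", {})
    if not isinstance(params, dict):
        problems.append("'params' must be a mapping")
    else:
        for key, value in params.items():
            if key not in DEFAULT_PARAMS:
                problems.append(f"params: unknown parameter '{key}'")
            elif key != "lipinski_bounds" and not isinstance(value, (int, float)):
                problems.append(f"params.{key}: expected a number, got {value!r}")
    if "output_dir" not in cfg:
        problems.append("missing 'output_dir'")
    return problems


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise any error tagged with the stage."""
    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: str | Path | dict, verbose: bool = False) -> dict[str, Any]:
    """Execute the full analysis; returns (and writes) the run report."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    cfg = load_config(config)
    params = {**DEFAULT_PARAMS, **(cfg.get("params") or {})}
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "params": params,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "warnings": [],
        "artifacts": {},
        "stages": {},
    }

    planted_hub = None
    if "synthetic" in cfg:
        with _stage("simulate"):
            synth_kwargs = dict(cfg.get("synthetic") or {})
            synth_kwargs.setdefault("seed", seed)
            synth = SynthConfig(**synth_kwargs)
            input_paths = write_study(synth, outdir / "synthetic_inputs")
            with open(input_paths["config"], encoding="utf-8") as handle:
                planted_hub = yaml.safe_load(handle).get("planted_hub")
            inputs = {k: str(v) for k, v in input_paths.items() if k != "config"}
            report["stages"]["simulate"] = {"planted_hub": planted_hub, "inputs": inputs}
    else:
        inputs = {k: str(v) for k, v in cfg["inputs"].items()}

    # 1. physicochemical screening (annotative)
    with _stage("screen"):
        roster = read_compound_table(inputs["compounds"])
        screen_report = screen(roster, tpsa_threshold=params["tpsa_threshold"])
        screen_path = outdir / "screen_report.tsv"
        screen_report.to_frame().to_csv(screen_path, sep="\t", index=False)
        report["artifacts"]["screen_report"] = str(screen_path)
        report["stages"]["screen"] = screen_report.summary

    # 2. two-stage target overlap
    with _stage("overlap"):
        table_a = read_prediction_table(inputs["predictions_a"], "sourceA")
        table_b = read_prediction_table(inputs["predictions_b"], "sourceB")
        set_a = TargetSet(label=table_a.source_name, members=table_a.targets)
        set_b = TargetSet(label=table_b.source_name, members=table_b.targets)
        disease = TargetSet.from_iterable("disease", read_symbol_list(inputs["disease_targets"]))
        overlap_result = two_stage_overlap(set_a, set_b, disease)
        venn_path = outdir / "venn.json"
        write_venn_json(overlap_result, venn_path)
        final_path = outdir / "final_targets.txt"
        write_symbol_list(overlap_result.final_targets.sorted_members(), final_path)
        report["artifacts"]["venn"] = str(venn_path)
        report["artifacts"]["final_targets"] = str(final_path)
        report["stages"]["overlap"] = {
            "source_a_size": len(set_a),
            "source_b_size": len(set_b),
            "union_size": overlap_result.union_size,
            "stage1_overlap": overlap_result.stage1.intersection_size,
            "disease_size": len(disease),
            "final_overlap": overlap_result.stage2.intersection_size,
        }
        final_targets = overlap_result.final_targets

    if not final_targets.members:
        report["warnings"].append("final target set is empty; downstream stages skipped")
        report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_report(report, outdir)
        return report

    # 3. pathway enrichment + key pathway
    with _stage("enrich"):
        db = read_gmt(inputs["pathways"])
        table = enrich(
            final_targets,
            db,
            background_size=int(params["background_size"]),
            alpha=params["alpha"],
        )
        enrich_path = outdir / "enrichment.tsv"
        table.to_frame().to_csv(enrich_path, sep="\t", index=False)
        bubble_path = outdir / "bubble.csv"
        bubble_data(table).to_csv(bubble_path, index=False)
        report["artifacts"]["enrichment"] = str(enrich_path)
        report["artifacts"]["bubble"] = str(bubble_path)
        stage: dict[str, Any] = {
            "n_pathways_hit": len(table),
            "n_significant": sum(1 for r in table.rows if r.significant),
        }
        if table.rows:
            stage["key_pathway"] = key_pathway(table)
            stage["min_rich_factor"] = round(min(r.rich_factor for r in table.rows), 4)
        else:
            report["warnings"].append("no pathway hit by the final target set")
        report["stages"]["enrich"] = stage

    # 4. tripartite network + degree analysis
    with _stage("pta"):
        pt_pairs = [(row.pathway_id, gene) for row in table.rows for gene in row.hit_genes]
        td_pairs = sorted(
            {
                (target, drug)
                for drug, target in (table_a.pairs | table_b.pairs)
                if target in final_targets.members
            }
        )
        pta = build_pta(pt_pairs, td_pairs)
        pta_path = outdir / "pta.graphml"
        write_graphml(pta, pta_path)
        degrees_path = outdir / "pta_degrees.tsv"
        degree_table(pta).to_csv(degrees_path, sep="\t", index=False)
        report["artifacts"]["pta"] = str(pta_path)
        report["artifacts"]["pta_degrees"] = str(degrees_path)
        summary = layer_degree_summary(pta)
        if "target" in summary:
            summary["target"].pop("breakdown", None)
        report["stages"]["pta"] = {
            "n_nodes": pta.number_of_nodes(),
            "n_edges": pta.number_of_edges(),
            "layers": summary,
        }

    # 5. PPI hub isolation
    with _stage("hub"):
        edge_list = read_edge_list(inputs["ppi_edges"], min_confidence=params["min_confidence"])
        hub_result = isolate_hub(edge_list, fraction=params["fraction"])
        full_path = outdir / "ppi_centrality.tsv"
        hub_result.full_table.to_csv(full_path, sep="\t", index=False)
        report["artifacts"]["ppi_centrality"] = str(full_path)
        if hub_result.sub_table is not None:
            sub_path = outdir / "subnetwork_centrality.tsv"
            hub_result.sub_table.to_csv(sub_path, sep="\t", index=False)
            report["artifacts"]["subnetwork_centrality"] = str(sub_path)
        if hub_result.subgraph is not None:
            sub_graphml = outdir / "subnetwork.graphml"
            write_graphml(hub_result.subgraph, sub_graphml)
            report["artifacts"]["subnetwork"] = str(sub_graphml)
        report["stages"]["hub"] = {
            "n_ppi_nodes": len(hub_result.full_table),
            "stage1_selected": list(hub_result.stage1.selected),
            "hub": list(hub_result.hub),
        }
        if planted_hub is not None:
            report["stages"]["hub"]["planted_hub"] = planted_hub
            report["stages"]["hub"]["planted_hub_recovered"] = list(hub_result.hub) == [planted_hub]

    # 6. docking triage
    with _stage("triage"):
        records = parse_scores(inputs["docking_scores"])
        triage = classify_binders(records, threshold=params["docking_threshold"])
        triage_path = outdir / "triage.tsv"
        triage.to_frame().to_csv(triage_path, sep="\t", index=False)
        report["artifacts"]["triage"] = str(triage_path)
        best = best_binder(records)
        report["stages"]["triage"] = {
            "n_records": len(records),
            "n_active": len(triage.actives),
            "n_inactive": len(triage.inactives),
            "threshold": params["docking_threshold"],
            "best_binder": best.ligand,
            "best_energy": best.binding_energy,
        }

    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    path = outdir / "report.json"
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, default=str)
        handle.write("\n")
    report["artifacts"]["report"] = str(path)
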