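"""End-to-end pipeline orchestration with a reproducible run manifest.

``run_pipeline`` chains the stages — ADME screening with rescues, optional
glycoside expansion, interaction gating with disease subsetting, construction
of the four bipartite networks — and writes every artifact (screening table,
gated interactions, network exports, markdown report, machine-readable
summary) plus a manifest recording the config snapshot, input checksums,
package version, seed and stage timings. Two runs from one manifest produce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .adme import RescueRule, ScreenConfig, apply_rescues, run_cascade
from .deglyco import DEFAULT_SUGAR_LIBRARY, expand_compound_table
from .io_model import (
    AnnotationTables,
    write_compound_table,
    write_interaction_table,
    write_report,
    read_compound_table,
    read_interaction_table,
    read_target_table,
)
from .networks import (
    build_bipartite,
    export_network,
    map_targets_to_pathways,
    write_node_attributes,
)
from .target_filter import GateConfig, filter_targets

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and record context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Input paths plus stage configuration for one pipeline run."""

    compounds: str
    targets: str
    interactions: str
    pathways: Optional[str] = None
    diseases: Optional[str] = None
    metabolite_map: Optional[str] = None
    dt_edges: Optional[str] = None
    disease_terms: tuple[str, ...] = ("inflammation",)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    gates: GateConfig = field(default_factory=GateConfig)
    rescues: tuple[RescueRule, ...] = ()
    expand_glycosides: bool = False
    seed: Optional[int] = None


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML file (keys mirror the dataclass)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    screen = ScreenConfig(**raw.pop("screen", {}))
    gates = GateConfig(**raw.pop("gates", {}))
    rescues = tuple(RescueRule(**r) for r in raw.pop("rescues", []))
    if "disease_terms" in raw:
        raw["disease_terms"] = tuple(raw["disease_terms"])
    return PipelineConfig(screen=screen, gates=gates, rescues=rescues, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_two_column(path: Path) -> dict[str, set[str]]:
    table: dict[str, set[str]] = {}
    lines = [
        ln
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    for ln in lines[1:]:
        key, _, value = ln.partition("\t")
        table.setdefault(key, set()).add(value)
    return table


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run screen -> (deglyco) -> targets -> networks -> report.

    Validates that every referenced input exists before writing anything.
    Returns a machine-readable summary dict (also written as summary.json).
    """
    out = Path(out_dir)
    inputs = {
        key: Path(p)
        for key, p in (
            ("compounds", config.compounds),
            ("targets", config.targets),
            ("interactions", config.interactions),
            ("pathways", config.pathways),
            ("diseases", config.diseases),
            ("metabolite_map", config.metabolite_map),
            ("dt_edges", config.dt_edges),
        )
        if p is not None
    }
    missing = {key: str(p) for key, p in inputs.items() if not p.exists()}
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "herbnet",
        "version": __version__,
        "seed": config.seed,
        "inputs": {key: {"path": str(p), "sha256": _sha256(p)} for key, p in inputs.items()},
        "config": {
            "screen": asdict(config.screen),
            "gates": asdict(config.gates),
            "rescues": [asdict(r) for r in config.rescues],
            "disease_terms": list(config.disease_terms),
            "expand_glycosides": config.expand_glycosides,
        },
        "stages": {},
    }

    def timed(stage: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate with the failing stage
            raise StageError(stage, str(exc)) from exc
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - start, 4)}
        return result

    # --- screen -----------------------------------------------------------
    compounds = timed("read", lambda: read_compound_table(inputs["compounds"]).records)
    if config.expand_glycosides:
        compounds, added = timed(
            "deglyco", lambda: expand_compound_table(compounds, DEFAULT_SUGAR_LIBRARY)
        )
        manifest["stages"]["deglyco"]["aglycones_added"] = added

    metabolites: dict[str, str] = {}
    if "metabolite_map" in inputs:
        map_lines = [
            ln
            for ln in inputs["metabolite_map"].read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        for ln in map_lines[1:]:
            parts = ln.split("\t")
            metabolites[parts[0]] = parts[1]

    def screen():
        result = run_cascade(compounds, config.screen)
        if config.rescues:
            result = apply_rescues(
                result, compounds, config.rescues, metabolites, config.screen
            )
        return result

    screening = timed("screen", screen)
    active = [c for c in compounds if c.compound_id in set(screening.final_set)]
    write_compound_table(active, out / "active_compounds.tsv")

    # --- targets ----------------------------------------------------------
    targets = timed("read_targets", lambda: read_target_table(inputs["targets"]).records)
    interactions = timed(
        "read_interactions", lambda: read_interaction_table(inputs["interactions"]).records
    )
    interactions = [
        rec for rec in interactions if rec.compound_id in set(screening.final_set)
    ]
    annotations = AnnotationTables(
        pathways=_load_two_column(inputs["pathways"]) if "pathways" in inputs else {},
        diseases=_load_two_column(inputs["diseases"]) if "diseases" in inputs else {},
        metabolites=metabolites,
    )
    funnel = timed(
        "targets",
        lambda: filter_targets(
            interactions, targets, annotations, list(config.disease_terms), config.gates
        ),
    )
    write_interaction_table(funnel["interactions"], out / "gated_interactions.tsv")

    # --- networks ---------------------------------------------------------
    def build_nets():
        nets = {}
        it_edges = sorted(
            {(rec.compound_id, rec.target_id) for rec in funnel["interactions"]}
        )
        nets["IT"] = build_bipartite(
            it_edges, "ingredients", "targets", name="ingredient-target"
        )
        if "dt_edges" in inputs:
            dt_lines = [
                ln
                for ln in inputs["dt_edges"].read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
            dt_pairs = [tuple(ln.split("\t")) for ln in dt_lines[1:]]
            nets["DT"] = build_bipartite(
                [(d, t) for d, t in dt_pairs], "drugs", "targets", name="drug-target"
            )
        if annotations.pathways:
            tp_edges, unmapped = map_targets_to_pathways(
                funnel["targets"], annotations.pathways
            )
            nets["TP"] = build_bipartite(
                tp_edges, "targets", "pathways", name="target-pathway"
            )
            manifest["stages"].setdefault("networks", {})["unmapped_targets"] = unmapped
        if annotations.diseases:
            td_edges = [
                (t, d)
                for d, members in sorted(annotations.diseases.items())
                for t in funnel["targets"]
                if t in members
            ]
            nets["TD"] = build_bipartite(
                td_edges, "targets", "diseases", name="target-disease"
            )
        return nets

    networks = timed("networks", build_nets)
    for key, net in networks.items():
        export_network(net, out / f"{key.lower()}_network.sif", "sif")
        export_network(net, out / f"{key.lower()}_network.graphml", "graphml")
        write_node_attributes(net, out / f"{key.lower()}_node_attributes.tsv")

    timed("report", lambda: write_report(screening, networks, out / "report.md"))

    summary = {
        "screening": {
            "stage_counts": screening.stage_counts,
            "threshold_survivors": len(screening.threshold_survivors),
            "rescued": [asdict(entry) for entry in screening.rescued],
            "final_active": len(screening.final_set),
        },
        "targets": {
            "final_targets": len(funnel["targets"]),
            "final_compounds": len(funnel["compounds"]),
            "gated_interactions": len(funnel["interactions"]),
        },
        "networks": {
            key: {
                "nodes": len(net.left) + len(net.right),
                "edges": len(net.edges),
            }
            for key, net in networks.items()
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
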