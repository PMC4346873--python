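"""Score gating and disease subsetting of compound-target interactions.

Predicted interactions come from a chemogenomic model that emits an SVM score
and a Random Forest score; both must clear their thresholds (SVM >= 0.8 AND
RF >= 0.7, inclusive boundaries). Literature-mined interactions are
experimentally supported and bypass the prediction gate unconditionally.
A docking fitness gate (score strictly greater than 40 by default, following
GOLD conventions) validates the surviving predictions; whether
literature-evidence interactions are also subjected to docking is
controlled by ``dock_literature`` (default False: only predictions are
docked). Finally targets are subset to those annotated with at least one
requested disease term — matching is exact-string against the annotation
table, synonym handling being the annotation curator's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_model import AnnotationTables, InteractionRecord, TargetRecord

__all__ = [
    "GateConfig",
    "DiseaseSubsetResult",
    "gate_predictions",
    "gate_docking",
    "disease_subset",
    "filter_targets",
]


@dataclass(frozen=True)
class GateConfig:
    """Thresholds for the interaction gates.

    SVM/RF boundaries are inclusive; the docking boundary is strict
    (``dock_strict=True``) so a score of exactly 40 is rejected.
    """

    svm_min: float = 0.8
    rf_min: float = 0.7
    dock_min: float = 40.0
    dock_strict: bool = True
    dock_literature: bool = False


@dataclass
class DiseaseSubsetResult:
    """Targets retained by disease annotation plus the orphan reports.

    ``orphan_compounds_before`` lists compounds that had no targets even
    before disease filtering; ``orphan_compounds_after`` those left with zero
    retained targets only once the disease subset is applied. Both views are
    surfaced because a pipeline may drop target-less compounds at either
    point.
    """

    targets: list[str]
    orphan_compounds_before: list[str] = field(default_factory=list)
    orphan_compounds_after: list[str] = field(default_factory=list)


def gate_predictions(
    interactions: Sequence[InteractionRecord], config: GateConfig = GateConfig()
) -> tuple[list[InteractionRecord], list[tuple[InteractionRecord, str]]]:
    """Retain literature records unconditionally and predicted records with
    svm >= svm_min AND rf >= rf_min. Predicted records missing either score
    are quarantined with a reason."""
    retained: list[InteractionRecord] = []
    quarantined: list[tuple[InteractionRecord, str]] = []
    for rec in interactions:
        if rec.source == "literature":
            retained.append(rec)
        elif rec.svm is None or rec.rf is None:
            quarantined.append((rec, "predicted record missing svm/rf score"))
        elif rec.svm >= config.svm_min and rec.rf >= config.rf_min:
            retained.append(rec)
    return retained, quarantined


def gate_docking(
    interactions: Sequence[InteractionRecord], config: GateConfig = GateConfig()
) -> tuple[list[InteractionRecord], list[tuple[InteractionRecord, str]]]:
    """Retain interactions whose docking score clears ``dock_min``.

    Strictly greater by default. Literature records skip the gate unless
    ``dock_literature`` is set. Records lacking a docking score are
    quarantined."""
    retained: list[InteractionRecord] = []
    quarantined: list[tuple[InteractionRecord, str]] = []
    for rec in interactions:
        if rec.source == "literature" and not config.dock_literature:
            retained.append(rec)
            continue
        if rec.dock is None:
            quarantined.append((rec, "missing docking score"))
        elif (rec.dock > config.dock_min) if config.dock_strict else (rec.dock >= config.dock_min):
            retained.append(rec)
        else:
            pass_mark = ">" if config.dock_strict else ">="
            quarantined.append((rec, f"dock={rec.dock} not {pass_mark} {config.dock_min}"))
    return retained, quarantined


def disease_subset(
    targets: Sequence[str],
    annotations: AnnotationTables,
    disease_terms: Sequence[str],
    interactions: Optional[Sequence[InteractionRecord]] = None,
) -> DiseaseSubsetResult:
    """Subset targets to those annotated with at least one requested disease.

    An unknown disease term fails listing the known terms. When the
    interaction table is supplied, compounds left without any retained target
    are reported (both before and after the disease filter is applied).
    """
    if not disease_terms:
        raise ValueError("disease_terms must not be empty")
    known = set(annotations.diseases)
    unknown = [term for term in disease_terms if term not in known]
    if unknown:
        raise ValueError(
            f"unknown disease term(s) {unknown}; known terms: {sorted(known)}"
        )
    annotated = set()
    for term in disease_terms:
        annotated |= annotations.diseases[term]
    retained = [t for t in targets if t in annotated]

    result = DiseaseSubsetResult(targets=retained)
    if interactions is not None:
        target_pool = set(targets)
        retained_set = set(retained)
        compounds = sorted({rec.compound_id for rec in interactions})
        for cid in compounds:
            linked = {rec.target_id for rec in interactions if rec.compound_id == cid}
            if not linked & target_pool:
                result.orphan_compounds_before.append(cid)
            if not linked & retained_set:
                result.orphan_compounds_after.append(cid)
    return result


def filter_targets(
    interactions: Sequence[InteractionRecord],
    targets: Sequence[TargetRecord],
    annotations: AnnotationTables,
    disease_terms: Sequence[str],
    config: GateConfig = GateConfig(),
) -> dict:
    """Full funnel: prediction gate -> disease subset -> docking gate.

    Each step's output is a subset of its input. Returns the retained
    interactions, the retained target ids, the compounds left in the final
    edge set and the per-step audit.
    """
    predicted_ok, quarantine_pred = gate_predictions(interactions, config)
    # interactions may reference targets by table id or by gene symbol
    known_ids = {t.target_id for t in targets} | {t.gene for t in targets}
    subset = disease_subset(
        sorted({rec.target_id for rec in predicted_ok if rec.target_id in known_ids}),
        annotations,
        disease_terms,
        interactions=predicted_ok,
    )
    disease_ok = [rec for rec in predicted_ok if rec.target_id in set(subset.targets)]
    docked_ok, quarantine_dock = gate_docking(disease_ok, config)
    final_targets = sorted({rec.target_id for rec in docked_ok})
    final_compounds = sorted({rec.compound_id for rec in docked_ok})
    return {
        "interactions": docked_ok,
        "targets": final_targets,
        "compounds": final_compounds,
        "disease_orphans": subset,
        "quarantined": quarantine_pred + quarantine_dock,
    }
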