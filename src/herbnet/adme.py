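"""Three-stage ADME screening cascade with declarative rescue rules.

Candidate ingredients pass, in configurable order, a drug-likeness stage
(DL >= 0.18), an oral-bioavailability stage (OB >= 30%) and a Caco-2
permeability stage (Caco-2 >= -0.4). All three thresholds are inclusive.
Because a pure property cascade misses ingredients that act through high
tissue content or through an absorbable metabolite, two rescue rules can
re-admit threshold failures afterwards:

* ``content_rescue`` — a failing compound whose measured herb content is at
  least ``content_min`` mg/g is re-admitted (the classic case is a poorly
  bioavailable triterpene present at high content).
* ``metabolite_rescue`` — a failing compound whose mapped gut metabolite
  itself passes a relaxed criteria set (by default OB and Caco-2 only, DL
  waived) is re-admitted, and the metabolite is admitted too.

Every admission is recorded in an audit trail; a record with a missing
property is excluded with reason "missing", never silently passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .io_model import CompoundRecord

__all__ = [
    "ScreenConfig",
    "RescueRule",
    "Exclusion",
    "RescueEntry",
    "ScreeningResult",
    "STAGES",
    "filter_stage",
    "run_cascade",
    "apply_rescues",
    "stage_survival_percent",
]

STAGES = ("dl", "ob", "caco2")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and stage order for the screening cascade.

    Defaults are the standard herbal-screening values: DL >= 0.18 (the mean
    drug-likeness of the DrugBank reference set), OB >= 30% and
    Caco-2 >= -0.4 (below which a compound is considered non-permeable).
    """

    dl_min: float = 0.18
    ob_min: float = 30.0
    caco2_min: float = -0.4
    stage_order: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if sorted(self.stage_order) != sorted(STAGES):
            raise ValueError(
                f"stage_order must be a permutation of {STAGES}, got {self.stage_order}"
            )

    def threshold(self, stage: str) -> float:
        return {"dl": self.dl_min, "ob": self.ob_min, "caco2": self.caco2_min}[stage]


@dataclass(frozen=True)
class RescueRule:
    """One declarative exception to the threshold cascade.

    ``content_rescue`` requires ``content_min`` (mg/g); there is no biological
    default, it must be supplied. ``metabolite_rescue`` uses the parent ->
    metabolite map passed to :func:`apply_rescues` and admits the parent when
    the metabolite passes the ``relaxed`` stage set; by default the metabolite
    must clear OB and Caco-2 while DL is waived. ``admit_parent=False``
    restricts admission to the metabolite only.
    """

    kind: str
    content_min: Optional[float] = None
    relaxed: tuple[str, ...] = ("ob", "caco2")
    admit_parent: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("content_rescue", "metabolite_rescue"):
            raise ValueError(f"unknown rescue kind {self.kind!r}")
        if self.kind == "content_rescue":
            if self.content_min is None or self.content_min <= 0:
                raise ValueError("content_rescue requires content_min > 0")
        if not set(self.relaxed) <= set(STAGES):
            raise ValueError(f"relaxed stages must be among {STAGES}")


@dataclass(frozen=True)
class Exclusion:
    compound_id: str
    stage: str
    value: Optional[float]
    threshold: float
    reason: str


@dataclass(frozen=True)
class RescueEntry:
    compound_id: str
    rule: str
    reason: str


@dataclass
class ScreeningResult:
    """Per-stage survivor sets, exclusion and rescue audit, final active set.

    Invariants: survivors nest (each stage a subset of the previous);
    ``final_set`` is the union of the last stage's survivors and the rescued
    ids; rescued ids never overlap the threshold survivors.
    """

    stage_survivors: dict[str, tuple[str, ...]]
    stage_counts: dict[str, int]
    excluded: list[Exclusion] = field(default_factory=list)
    rescued: list[RescueEntry] = field(default_factory=list)
    final_set: tuple[str, ...] = ()

    @property
    def threshold_survivors(self) -> tuple[str, ...]:
        if not self.stage_survivors:
            return ()
        return next(reversed(self.stage_survivors.values()))


def _value(record: CompoundRecord, stage: str) -> Optional[float]:
    return {"dl": record.dl, "ob": record.ob, "caco2": record.caco2}[stage]


def filter_stage(
    records: Sequence[CompoundRecord], stage: str, config: ScreenConfig
) -> tuple[list[CompoundRecord], list[Exclusion]]:
    """Apply one threshold stage: survivor iff property >= threshold (inclusive).

    Records with a missing property are excluded with reason "missing".
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    threshold = config.threshold(stage)
    survivors: list[CompoundRecord] = []
    excluded: list[Exclusion] = []
    for record in records:
        value = _value(record, stage)
        if value is None:
            excluded.append(Exclusion(record.compound_id, stage, None, threshold, "missing"))
        elif value >= threshold:
            survivors.append(record)
        else:
            excluded.append(
                Exclusion(
                    record.compound_id, stage, value, threshold,
                    f"{stage}={value} < {threshold}",
                )
            )
    return survivors, excluded


def run_cascade(
    records: Sequence[CompoundRecord], config: ScreenConfig = ScreenConfig()
) -> ScreeningResult:
    """Run the stages in config order, recording survivors and counts per stage.

    The final AND-set is independent of the stage order; intermediate counts
    are not.
    """
    current = list(records)
    stage_survivors: dict[str, tuple[str, ...]] = {}
    stage_counts: dict[str, int] = {}
    all_excluded: list[Exclusion] = []
    for stage in config.stage_order:
        current, excluded = filter_stage(current, stage, config)
        stage_survivors[stage] = tuple(r.compound_id for r in current)
        stage_counts[stage] = len(current)
        all_excluded.extend(excluded)
    return ScreeningResult(
        stage_survivors=stage_survivors,
        stage_counts=stage_counts,
        excluded=all_excluded,
        final_set=tuple(r.compound_id for r in current),
    )


def _passes_relaxed(
    record: CompoundRecord, stages: Iterable[str], config: ScreenConfig
) -> bool:
    for stage in stages:
        value = _value(record, stage)
        if value is None or value < config.threshold(stage):
            return False
    return True


def apply_rescues(
    result: ScreeningResult,
    records: Sequence[CompoundRecord],
    rules: Sequence[RescueRule],
    metabolite_map: Optional[Mapping[str, str]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> ScreeningResult:
    """Apply rescue rules to a cascade result, returning the final result.

    Rescued ids are appended to the audit with rule and reason; the final set
    is the ordered union of threshold survivors and rescued ids. A rescue rule
    that names a compound absent from the table is an error.
    """
    by_id = {r.compound_id: r for r in records}
    survivors = set(result.threshold_survivors)
    admitted: dict[str, RescueEntry] = {}

    def admit(cid: str, rule: str, reason: str) -> None:
        if cid not in survivors and cid not in admitted:
            admitted[cid] = RescueEntry(cid, rule, reason)

    for rule in rules:
        if rule.kind == "content_rescue":
            for record in records:
                if record.compound_id in survivors:
                    continue
                if record.content is not None and record.content >= rule.content_min:
                    admit(
                        record.compound_id,
                        rule.kind,
                        f"content {record.content} mg/g >= {rule.content_min} mg/g",
                    )
        elif rule.kind == "metabolite_rescue":
            if metabolite_map is None:
                raise ValueError("metabolite_rescue requires a metabolite map")
            for parent_id, metabolite_id in metabolite_map.items():
                if parent_id not in by_id:
                    raise ValueError(f"metabolite map names unknown compound {parent_id!r}")
                if metabolite_id not in by_id:
                    raise ValueError(f"metabolite map names unknown compound {metabolite_id!r}")
                if parent_id in survivors:
                    continue
                metabolite = by_id[metabolite_id]
                if _passes_relaxed(metabolite, rule.relaxed, config):
                    relaxed = "+".join(rule.relaxed)
                    if rule.admit_parent:
                        admit(
                            parent_id,
                            rule.kind,
                            f"metabolite {metabolite_id} passes {relaxed}",
                        )
                    admit(
                        metabolite_id,
                        rule.kind,
                        f"absorbable metabolite of {parent_id} (passes {relaxed})",
                    )

    order = [r.compound_id for r in records]
    rescued = [admitted[cid] for cid in order if cid in admitted]
    final = tuple(
        cid for cid in order if cid in survivors or cid in admitted
    )
    return replace(result, rescued=list(result.rescued) + rescued, final_set=final)


def stage_survival_percent(result: ScreeningResult, stage: str) -> int:
    """Percent of the previous stage's survivors that clear ``stage``,
    rounded to the nearest integer (the scale funnel statements are quoted
    on, e.g. "about 46%")."""
    stages = list(result.stage_counts)
    if stage not in stages:
        raise ValueError(f"stage {stage!r} not in result (has {stages})")
    idx = stages.index(stage)
    if idx == 0:
        raise ValueError("no upstream stage to compare against")
    before = result.stage_counts[stages[idx - 1]]
    if before == 0:
        raise ValueError("upstream stage has no survivors")
    return round(100 * result.stage_counts[stage] / before)
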