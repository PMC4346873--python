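"""Domain types and tabular I/O for the herbal network-pharmacology pipeline.

Every other module consumes the record types defined here. Tables are plain
UTF-8 CSV/TSV with documented headers; the delimiter is auto-detected from the
file extension and can be overridden. Hand-curated ingredient tables are messy,
so malformed *rows* are quarantined with a reason rather than aborting the run;
structural problems (missing columns, duplicate keys) abort immediately.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "CompoundRecord",
    "TargetRecord",
    "InteractionRecord",
    "AnnotationTables",
    "ParsedTable",
    "SchemaError",
    "read_compound_table",
    "read_target_table",
    "read_interaction_table",
    "write_compound_table",
    "write_target_table",
    "write_interaction_table",
    "write_report",
]


class SchemaError(ValueError):
    """A structural problem with an input table (missing column, duplicate key)."""


@dataclass(frozen=True)
class CompoundRecord:
    """One herbal ingredient with its ADME properties and annotations.

    ``ob`` is oral bioavailability on the 0-100 percent scale, ``caco2`` the
    log apparent permeability across a Caco-2 monolayer (may be negative) and
    ``dl`` the dimensionless drug-likeness index in [0, 1]. ``content`` is the
    measured content in mg per g dry herb where known. Aglycones produced by
    deglycosylation carry ``is_aglycone=True`` and point back at their
    glycoside parent via ``parent_id``.
    """

    compound_id: str
    name: str
    ob: Optional[float] = None
    caco2: Optional[float] = None
    dl: Optional[float] = None
    smiles: Optional[str] = None
    content: Optional[float] = None
    bioactivities: tuple[str, ...] = ()
    is_aglycone: bool = False
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ob is not None and self.ob < 0:
            raise ValueError(f"{self.compound_id}: ob must be >= 0, got {self.ob}")
        if self.dl is not None and not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.compound_id}: dl must be in [0,1], got {self.dl}")
        if self.is_aglycone and self.parent_id is None:
            raise ValueError(f"{self.compound_id}: aglycone records need a parent_id")


@dataclass(frozen=True)
class TargetRecord:
    """One protein target: gene symbol, protein name and UniProt accession.

    ``uniprot`` is stored verbatim from the source table, with no validation
    against external services. ``shared_with_drugs`` flags targets that are
    also hit by approved drugs in the reference drug-target table.
    """

    target_id: str
    gene: str
    protein_name: str = ""
    uniprot: str = ""
    shared_with_drugs: bool = False
    disease_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"{self.target_id}: gene symbol must be non-empty")


VALID_SOURCES = ("literature", "predicted")


@dataclass(frozen=True)
class InteractionRecord:
    """One compound-target pair with its evidence source and scores.

    ``source`` is ``literature`` (experimentally supported, mined from
    databases) or ``predicted`` (chemogenomic model output). Predicted records
    must carry SVM and RF scores in [0, 1]; ``dock`` is an unbounded
    nonnegative docking fitness score when docking was performed.
    """

    compound_id: str
    target_id: str
    source: str = "predicted"
    svm: Optional[float] = None
    rf: Optional[float] = None
    dock: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"{self.compound_id}-{self.target_id}: source must be one of "
                f"{VALID_SOURCES}, got {self.source!r}"
            )


@dataclass
class AnnotationTables:
    """Local annotation lookups: pathway/disease memberships, metabolite and drug maps."""

    pathways: dict[str, set[str]] = field(default_factory=dict)
    diseases: dict[str, set[str]] = field(default_factory=dict)
    metabolites: dict[str, str] = field(default_factory=dict)
    drugs: dict[str, set[str]] = field(default_factory=dict)

    def unresolved(
        self,
        known_compounds: Iterable[str] = (),
        known_targets: Iterable[str] = (),
    ) -> list[str]:
        """Return warnings for annotation ids that do not resolve against the
        loaded compound/target tables. Unresolvable ids are reported, never
        silently dropped."""
        compounds = set(known_compounds)
        targets = set(known_targets)
        warnings: list[str] = []
        if targets:
            for table_name, table in (("pathway", self.pathways), ("disease", self.diseases)):
                for key, members in sorted(table.items()):
                    for tid in sorted(members - targets):
                        warnings.append(f"{table_name} {key!r}: unknown target {tid!r}")
        if compounds:
            for parent, metabolite in sorted(self.metabolites.items()):
                if parent not in compounds:
                    warnings.append(f"metabolite map: unknown parent {parent!r}")
                if metabolite not in compounds:
                    warnings.append(f"metabolite map: unknown metabolite {metabolite!r}")
        return warnings


@dataclass
class ParsedTable:
    """Records parsed from a table plus the rows quarantined with a reason.

    Invariant: rows in = len(records) + len(quarantined); nothing is dropped
    silently.
    """

    records: list
    quarantined: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# reading


def _delimiter(path: Path, dialect: Optional[str]) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_rows(path: Path, delim: str) -> tuple[list[str], list[dict]]:
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(io.StringIO("".join(lines)), delimiter=delim)
    if reader.fieldnames is None:
        return [], []
    return list(reader.fieldnames), list(reader)


def _require(columns: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _num(raw: Optional[str]) -> Optional[float]:
    if raw is None or raw.strip() == "":
        return None
    value = float(raw.replace("−", "-"))  # tolerate unicode minus
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {raw!r}")
    return value


def read_compound_table(path, dialect: Optional[str] = None) -> ParsedTable:
    """Read a compound property table (id, name, ob, caco2, dl, optional
    smiles/content/bioactivities columns).

    Rows with a non-numeric property are quarantined with a reason; a missing
    required column raises :class:`SchemaError` naming the column, as does a
    duplicate compound_id.
    """
    path = Path(path)
    columns, rows = _read_rows(path, _delimiter(path, dialect))
    if rows or columns:
        _require(columns, ["compound_id", "name", "ob", "caco2", "dl"], path)
    records: list[CompoundRecord] = []
    quarantined: list[tuple[int, str]] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(rows, start=2):  # 1-based, after header
        cid = (row.get("compound_id") or "").strip()
        if not cid:
            quarantined.append((i, "empty compound_id"))
            continue
        if cid in seen:
            raise SchemaError(f"{path}: duplicate compound_id {cid!r} (rows {seen[cid]}, {i})")
        seen[cid] = i
        try:
            bio = tuple(
                tok.strip()
                for tok in (row.get("bioactivities") or "").split(";")
                if tok.strip()
            )
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=(row.get("name") or "").strip(),
                    ob=_num(row.get("ob")),
                    caco2=_num(row.get("caco2")),
                    dl=_num(row.get("dl")),
                    smiles=(row.get("smiles") or "").strip() or None,
                    content=_num(row.get("content")),
                    bioactivities=bio,
                    is_aglycone=(row.get("is_aglycone") or "").strip() in ("1", "true", "True"),
                    parent_id=(row.get("parent_id") or "").strip() or None,
                )
            )
        except ValueError as exc:
            quarantined.append((i, str(exc)))
    return ParsedTable(records, quarantined)


def read_target_table(path, dialect: Optional[str] = None) -> ParsedTable:
    """Read a target table (target_id, gene, protein_name, uniprot).

    Duplicate target_ids are a hard failure listing the duplicates; UniProt
    accessions are taken verbatim.
    """
    path = Path(path)
    columns, rows = _read_rows(path, _delimiter(path, dialect))
    if rows or columns:
        _require(columns, ["target_id", "gene"], path)
    ids = [(row.get("target_id") or "").strip() for row in rows]
    dupes = sorted({t for t in ids if t and ids.count(t) > 1})
    if dupes:
        raise SchemaError(f"{path}: duplicate target_id(s) {dupes}")
    records: list[TargetRecord] = []
    quarantined: list[tuple[int, str]] = []
    for i, row in enumerate(rows, start=2):
        tid = (row.get("target_id") or "").strip()
        try:
            records.append(
                TargetRecord(
                    target_id=tid,
                    gene=(row.get("gene") or "").strip(),
                    protein_name=(row.get("protein_name") or "").strip(),
                    uniprot=(row.get("uniprot") or "").strip(),
                    shared_with_drugs=(row.get("shared_with_drugs") or "").strip()
                    in ("1", "true", "True"),
                    disease_tags=tuple(
                        tok.strip()
                        for tok in (row.get("disease_tags") or "").split(";")
                        if tok.strip()
                    ),
                )
            )
        except ValueError as exc:
            quarantined.append((i, str(exc)))
    return ParsedTable(records, quarantined)


def read_interaction_table(path, dialect: Optional[str] = None) -> ParsedTable:
    """Read a compound-target interaction table
    (compound_id, target_id, source, svm, rf, dock)."""
    path = Path(path)
    columns, rows = _read_rows(path, _delimiter(path, dialect))
    if rows or columns:
        _require(columns, ["compound_id", "target_id"], path)
    records: list[InteractionRecord] = []
    quarantined: list[tuple[int, str]] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=2):
        key = (
            (row.get("compound_id") or "").strip(),
            (row.get("target_id") or "").strip(),
        )
        if key in seen:
            raise SchemaError(f"{path}: duplicate interaction {key}")
        seen.add(key)
        try:
            records.append(
                InteractionRecord(
                    compound_id=key[0],
                    target_id=key[1],
                    source=(row.get("source") or "predicted").strip(),
                    svm=_num(row.get("svm")),
                    rf=_num(row.get("rf")),
                    dock=_num(row.get("dock")),
                )
            )
        except ValueError as exc:
            quarantined.append((i, str(exc)))
    return ParsedTable(records, quarantined)


# ---------------------------------------------------------------------------
# writing


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(value)  # full precision round trip


def write_compound_table(records: Iterable[CompoundRecord], path, dialect=None) -> None:
    path = Path(path)
    delim = _delimiter(path, dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(
            ["compound_id", "name", "ob", "caco2", "dl", "smiles", "content",
             "bioactivities", "is_aglycone", "parent_id"]
        )
        for r in records:
            writer.writerow(
                [r.compound_id, r.name, _fmt(r.ob), _fmt(r.caco2), _fmt(r.dl),
                 r.smiles or "", _fmt(r.content), "; ".join(r.bioactivities),
                 "1" if r.is_aglycone else "", r.parent_id or ""]
            )


def write_target_table(records: Iterable[TargetRecord], path, dialect=None) -> None:
    path = Path(path)
    delim = _delimiter(path, dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(
            ["target_id", "gene", "protein_name", "uniprot", "shared_with_drugs",
             "disease_tags"]
        )
        for r in records:
            writer.writerow(
                [r.target_id, r.gene, r.protein_name, r.uniprot,
                 "1" if r.shared_with_drugs else "0", "; ".join(r.disease_tags)]
            )


def write_interaction_table(records: Iterable[InteractionRecord], path, dialect=None) -> None:
    path = Path(path)
    delim = _delimiter(path, dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["compound_id", "target_id", "source", "svm", "rf", "dock"])
        for r in records:
            writer.writerow(
                [r.compound_id, r.target_id, r.source, _fmt(r.svm), _fmt(r.rf),
                 _fmt(r.dock)]
            )


# ---------------------------------------------------------------------------
# report


def write_report(screening_result, networks: Mapping[str, object], path) -> None:
    """Write a human-readable markdown run report.

    Sections: per-stage screening counts with the rescue audit, then one
    section per network with node/edge counts, mean degrees (printed at 2
    decimals) and hub lists. Ordering is deterministic (degree descending,
    then lexicographic id) so regenerating the report on the same inputs is
    byte-identical.
    """
    from . import networks as net_mod  # local import to avoid a cycle

    lines: list[str] = ["# Pipeline report", "", "## Screening", ""]
    if screening_result is not None:
        for stage, count in screening_result.stage_counts.items():
            lines.append(f"- after `{stage}` stage: {count} compounds")
        lines.append(f"- threshold survivors: {len(screening_result.threshold_survivors)}")
        lines.append(f"- final active set: {len(screening_result.final_set)} compounds")
        lines.append("")
        if screening_result.rescued:
            lines.append("### Rescue audit")
            lines.append("")
            for entry in screening_result.rescued:
                lines.append(f"- {entry.compound_id} via {entry.rule}: {entry.reason}")
            lines.append("")
        if screening_result.excluded:
            lines.append("### Exclusions")
            lines.append("")
            for exc in sorted(screening_result.excluded, key=lambda e: (e.stage, e.compound_id)):
                lines.append(
                    f"- {exc.compound_id} at `{exc.stage}`: {exc.reason}"
                )
            lines.append("")
    for name in sorted(networks):
        net = networks[name]
        summary = net_mod.degree_summary(net)
        lines.append(f"## Network: {name}")
        lines.append("")
        lines.append(
            f"- {len(net.left) + len(net.right)} nodes "
            f"({len(net.left)} {net.left_role} + {len(net.right)} {net.right_role}), "
            f"{len(net.edges)} edges"
        )
        lines.append(
            f"- mean degree {summary.mean_degree_all:.2f} "
            f"({net.left_role} {summary.mean_degree_left:.2f}, "
            f"{net.right_role} {summary.mean_degree_right:.2f})"
        )
        for partition in ("left", "right"):
            role = getattr(net, f"{partition}_role")
            hubs = net_mod.find_hubs(net, partition)
            if hubs:
                listed = ", ".join(f"{node} ({deg})" for node, deg in hubs)
                lines.append(f"- {role} hubs (degree > mean): {listed}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
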