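"""Synthetic tables with controlled pass rates, plus the packaged fixtures.

The real screening inputs (the full 389-ingredient property table, the
prediction and docking score tables) were never published, so the pipeline is
exercised on two kinds of data:

* **Synthetic tables.** Property values are drawn so that the marginal
  probability of clearing each ADME threshold equals a requested pass rate:
  the number of passers is binomial (or exact with ``exact=True``) and values
  are then sampled from the base distribution conditioned on the passing or
  failing side of the threshold. Defaults reproduce the published funnel
  shape: 389 compounds with pass rates 134/389 (DL), 61/134 (OB) and 26/61
  (Caco-2). All randomness flows through one seeded generator; identical
  config and seed give identical tables.

* **Packaged fixtures.** Transcriptions of the published ingredient and
  target tables plus reconstruction fixtures (edge wirings satisfying every
  printed degree constraint, with unpublished wiring filled
  deterministically). Fixture files are checksummed; any edit fails loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_model import (
    AnnotationTables,
    CompoundRecord,
    InteractionRecord,
    ParsedTable,
    TargetRecord,
    read_compound_table,
    read_interaction_table,
    read_target_table,
)

__all__ = [
    "GeneratorConfig",
    "FixtureIntegrityError",
    "generate_compound_table",
    "generate_interaction_table",
    "load_fixture",
    "load_annotations",
    "FIXTURE_NAMES",
]


# published funnel: 389 ingredients -> 134 (DL) -> 61 (OB) -> 26 (Caco-2)
_FUNNEL = (389, 134, 61, 26)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic table generator.

    Pass rates are the marginal probabilities of clearing each threshold
    (defaults: the published funnel fractions). Distribution shape parameters
    fix the base distributions the conditional values are drawn from:
    OB a truncated normal on [0, 100], Caco-2 a normal, DL a beta. The seed
    is mandatory — there is no unseeded mode.
    """

    seed: int
    n_compounds: int = _FUNNEL[0]
    p_dl: float = _FUNNEL[1] / _FUNNEL[0]
    p_ob: float = _FUNNEL[2] / _FUNNEL[1]
    p_caco2: float = _FUNNEL[3] / _FUNNEL[2]
    exact: bool = False
    dl_min: float = 0.18
    ob_min: float = 30.0
    caco2_min: float = -0.4
    ob_mean: float = 30.0
    ob_sd: float = 20.0
    caco2_mean: float = -0.4
    caco2_sd: float = 0.8
    dl_a: float = 1.2
    dl_b: float = 2.5
    n_targets: int = 43
    edge_density: float = 82 / (11 * 43)
    svm_range: tuple[float, float] = (0.0, 1.0)
    rf_range: tuple[float, float] = (0.0, 1.0)
    dock_range: tuple[float, float] = (0.0, 80.0)

    def __post_init__(self) -> None:
        for name, p in (("p_dl", self.p_dl), ("p_ob", self.p_ob), ("p_caco2", self.p_caco2)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError(f"edge_density must be in [0,1], got {self.edge_density}")
        if self.n_compounds < 0 or self.n_targets < 0:
            raise ValueError("table sizes must be nonnegative")


def _sample_split(
    rng: np.random.Generator,
    n: int,
    p: float,
    dist,
    threshold: float,
    exact: bool,
) -> np.ndarray:
    """Draw n values whose probability of being >= threshold is p.

    The pass/fail label is decided first (binomially, or exactly round(p*n)
    with ``exact``); values are then drawn from ``dist`` conditioned on the
    labelled side via inverse-CDF sampling. Degenerate p of 0 or 1 simply
    samples one side.
    """
    if exact:
        k = int(round(p * n))
    else:
        k = int(rng.binomial(n, p))
    passing = np.zeros(n, dtype=bool)
    passing[rng.permutation(n)[:k]] = True
    c = float(dist.cdf(threshold))
    u = rng.uniform(size=n)
    values = np.empty(n)
    # conditional inverse CDF: failers land in [0, c), passers in [c, 1]
    values[~passing] = dist.ppf(u[~passing] * c) if c > 0 else threshold
    values[passing] = dist.ppf(c + u[passing] * (1.0 - c)) if c < 1 else threshold
    return values


def generate_compound_table(config: GeneratorConfig) -> list[CompoundRecord]:
    """Generate a synthetic compound property table.

    Reproducible under a fixed seed; the empirical pass rates at the
    thresholds converge to the configured ones as n grows (and are exact up
    to rounding with ``exact=True``). Compound ids are systematic
    (C0001, ...) to avoid collision with real ingredient names.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    ob_dist = stats.truncnorm(
        (0.0 - config.ob_mean) / config.ob_sd,
        (100.0 - config.ob_mean) / config.ob_sd,
        loc=config.ob_mean,
        scale=config.ob_sd,
    )
    caco2_dist = stats.norm(loc=config.caco2_mean, scale=config.caco2_sd)
    dl_dist = stats.beta(config.dl_a, config.dl_b)
    dl = _sample_split(rng, n, config.p_dl, dl_dist, config.dl_min, config.exact)
    ob = _sample_split(rng, n, config.p_ob, ob_dist, config.ob_min, config.exact)
    caco2 = _sample_split(rng, n, config.p_caco2, caco2_dist, config.caco2_min, config.exact)
    dl = np.clip(dl, 0.0, 1.0)
    width = max(4, len(str(n)))
    return [
        CompoundRecord(
            compound_id=f"C{i + 1:0{width}d}",
            name=f"synthetic compound {i + 1}",
            ob=float(ob[i]),
            caco2=float(caco2[i]),
            dl=float(dl[i]),
        )
        for i in range(n)
    ]


def generate_interaction_table(
    config: GeneratorConfig,
    compounds: Sequence[CompoundRecord],
    targets: Sequence[TargetRecord],
) -> list[InteractionRecord]:
    """Sample compound-target edges at the configured density with uniform
    scores in the configured ranges. Density 1 yields the complete bipartite
    edge set; density 0 an empty table."""
    rng = np.random.default_rng(config.seed + 1)
    records: list[InteractionRecord] = []
    for compound in compounds:
        mask = rng.uniform(size=len(targets)) < config.edge_density
        for target, hit in zip(targets, mask):
            if not hit:
                continue
            records.append(
                InteractionRecord(
                    compound_id=compound.compound_id,
                    target_id=target.target_id,
                    source="predicted",
                    svm=float(rng.uniform(*config.svm_range)),
                    rf=float(rng.uniform(*config.rf_range)),
                    dock=float(rng.uniform(*config.dock_range)),
                )
            )
    return records


# ---------------------------------------------------------------------------
# packaged fixtures


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its locked checksum."""


FIXTURE_NAMES = (
    "table1",
    "table2",
    "it_edges",
    "dt_edges",
    "pathways",
    "diseases",
    "metabolite_map",
)

_FIXTURE_FILES = {name: f"{name}.tsv" for name in FIXTURE_NAMES}

# sha256 of the packaged transcriptions; any edit to a fixture fails the suite
FIXTURE_SHA256 = {
    "table1": "12cd2758bb29b530bf7a8ece9866288550e971bb113585be2a0ce1b295597443",
    "table2": "e66b847f3b054fc133f8fe70314bdf537c3b62ad027a20d658c1abc0f802968d",
    "it_edges": "44addf4d0c5eb2de18c7b3383e12accbcfaca8a243f00a61f3e832cd271cd99b",
    "dt_edges": "095454760a9d27daa4198b4e02eec73b6cad587884527337be4de238a3ec3aa3",
    "pathways": "6babf957089a23769811c76aff41bc1a1b88bbd185a39925775aee0576a9ae9f",
    "diseases": "d790a96daf61ce5e9966bc4aa87030e2961226f1a588684c0a95889cca122d5c",
    "metabolite_map": "baf27d70673f27ea5ea72a41acb75815ed62c8b293b6f3656578932cf64a15d7",
}


def fixture_path(name: str) -> Path:
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}")
    return Path(str(resources.files("herbnet") / "data" / _FIXTURE_FILES[name]))


def _verify(name: str, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(
            f"fixture {name!r} checksum mismatch: expected "
            f"{FIXTURE_SHA256[name]}, got {digest}"
        )


def load_fixture(name: str):
    """Load a packaged fixture by name, verifying its checksum.

    Returns a :class:`ParsedTable` for the record tables (``table1``,
    ``table2``, ``it_edges``), an edge list for ``dt_edges``, a
    ``{name: set of target ids}`` mapping for ``pathways`` and ``diseases``
    and a ``{parent: metabolite}`` mapping for ``metabolite_map``.
    """
    path = fixture_path(name)
    _verify(name, path)
    if name == "table1":
        return read_compound_table(path)
    if name == "table2":
        return read_target_table(path)
    if name == "it_edges":
        return read_interaction_table(path)
    if name == "dt_edges":
        lines = [
            ln
            for ln in path.read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        return [tuple(ln.split("\t")) for ln in lines[1:]]
    if name in ("pathways", "diseases"):
        table: dict[str, set[str]] = {}
        lines = [
            ln
            for ln in path.read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        for ln in lines[1:]:
            key, _, target = ln.partition("\t")
            table.setdefault(key, set()).add(target)
        return table
    if name == "metabolite_map":
        lines = [
            ln
            for ln in path.read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        return {ln.split("\t")[0]: ln.split("\t")[1] for ln in lines[1:]}
    raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}")


def load_annotations() -> AnnotationTables:
    """All annotation fixtures bundled into one :class:`AnnotationTables`."""
    drugs: dict[str, set[str]] = {}
    for drug, target in load_fixture("dt_edges"):
        drugs.setdefault(drug, set()).add(target)
    return AnnotationTables(
        pathways=load_fixture("pathways"),
        diseases=load_fixture("diseases"),
        metabolites=load_fixture("metabolite_map"),
        drugs=drugs,
    )
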