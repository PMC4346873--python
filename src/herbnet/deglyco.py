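"""Rule-based enumeration of aglycones from glycosidic ingredients.

Deglycosylation by colonic bacteria is a critical step in the absorption of
herbal glycosides: the sugar-free aglycone, not the glycoside, is usually the
absorbable species. This module emulates glycosidase hydrolysis as a graph
rewrite: a library of sugar SMARTS patterns marks the exocyclic O-glycosidic
oxygen and the anomeric ring carbon; cleaving that bond releases the sugar,
leaves the oxygen on the aglycone as a hydroxyl, and the product is
re-canonicalized. Multi-sugar glycosides are hydrolyzed to fixpoint by
default (single-step products available via ``max_steps=1``).

Only O-glycosides are cleaved. C-glycosides are enzymatically resistant and
excluded by construction, and glycosyl *esters* are excluded from the
patterns because ester cleavage is an esterase reaction handled by the
metabolite map of the screening stage, not by this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_model import CompoundRecord

__all__ = [
    "SugarPattern",
    "DEFAULT_SUGAR_LIBRARY",
    "load_sugar_library",
    "enumerate_aglycones",
    "expand_compound_table",
]


@dataclass(frozen=True)
class SugarPattern:
    """A cleavable sugar substructure.

    ``smarts`` must carry two mapped atoms: map 1 is the exocyclic glycosidic
    oxygen (stays with the aglycone as a hydroxyl), map 2 the anomeric ring
    carbon (leaves with the sugar). The leading ``[#6;!$([#6]=O)]`` atom
    excludes glycosyl esters; anomeric stereochemistry is deliberately not
    specified so both anomers match.
    """

    name: str
    smarts: str

    def __post_init__(self) -> None:
        from rdkit import Chem

        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"sugar pattern {self.name!r}: unparseable SMARTS")
        maps = {a.GetAtomMapNum() for a in patt.GetAtoms()}
        if not {1, 2} <= maps:
            raise ValueError(
                f"sugar pattern {self.name!r}: SMARTS must map the glycosidic "
                "oxygen as :1 and the anomeric carbon as :2"
            )

    def query(self):
        from rdkit import Chem

        return Chem.MolFromSmarts(self.smarts)


#: Common herbal sugars. Hexose covers glucose/galactose/mannose (constitution
#: is identical once anomeric stereo is ignored); deoxyhexose covers rhamnose
#: and fucose; pentose covers arabinose and xylose. Rutinose and other
#: disaccharides need no dedicated pattern: fixpoint iteration strips them
#: sugar by sugar.
DEFAULT_SUGAR_LIBRARY: tuple[SugarPattern, ...] = (
    SugarPattern(
        "hexose",
        "[#6;!$([#6]=O)][OX2;!R:1][CH:2]1O[CH](CO)[CH](O)[CH](O)[CH]1O",
    ),
    SugarPattern(
        "deoxyhexose",
        "[#6;!$([#6]=O)][OX2;!R:1][CH:2]1O[CH](C)[CH](O)[CH](O)[CH]1O",
    ),
    SugarPattern(
        "pentose",
        "[#6;!$([#6]=O)][OX2;!R:1][CH:2]1OC[CH](O)[CH](O)[CH]1O",
    ),
    SugarPattern(
        "hexuronic_acid",
        "[#6;!$([#6]=O)][OX2;!R:1][CH:2]1O[CH](C(=O)O)[CH](O)[CH](O)[CH]1O",
    ),
)


def load_sugar_library(path) -> tuple[SugarPattern, ...]:
    """Load an extensible sugar library from a plain-text file of
    ``name<TAB>SMARTS`` lines (``#`` comments allowed)."""
    patterns = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, smarts = line.partition("\t")
        patterns.append(SugarPattern(name.strip(), smarts.strip()))
    return tuple(patterns)


def _cleave_once(mol, library: Sequence[SugarPattern]) -> set[str]:
    """All single-cleavage aglycone products of ``mol``, as canonical SMILES.

    For each sugar match the O-glycosidic bond is broken; the fragment
    containing the glycosidic oxygen is the aglycone (the oxygen becomes a
    hydroxyl via implicit-H bookkeeping). Products that fail sanitization
    are dropped.
    """
    from rdkit import Chem

    products: set[str] = set()
    for pattern in library:
        query = pattern.query()
        o_pos = c_pos = None
        for atom in query.GetAtoms():
            if atom.GetAtomMapNum() == 1:
                o_pos = atom.GetIdx()
            elif atom.GetAtomMapNum() == 2:
                c_pos = atom.GetIdx()
        for match in mol.GetSubstructMatches(query):
            o_idx, c_idx = match[o_pos], match[c_pos]
            editable = Chem.RWMol(mol)
            editable.RemoveBond(o_idx, c_idx)
            try:
                cleaved = editable.GetMol()
                Chem.SanitizeMol(cleaved)
            except Exception:
                continue  # sanitization failure: drop this product
            frag_atom_ids = Chem.GetMolFrags(cleaved)
            frag_mols = Chem.GetMolFrags(cleaved, asMols=True, sanitizeFrags=True)
            for atom_ids, frag in zip(frag_atom_ids, frag_mols):
                if o_idx in atom_ids:
                    products.add(Chem.MolToSmiles(frag))
    return products


def enumerate_aglycones(
    smiles: str,
    sugar_library: Sequence[SugarPattern] = DEFAULT_SUGAR_LIBRARY,
    max_steps: Optional[int] = None,
) -> set[str]:
    """Enumerate the aglycones of a glycoside as canonical SMILES.

    Hydrolysis iterates to fixpoint (every matched sugar eventually removed,
    in any order — the result is order independent) and only fully
    deglycosylated products are returned; ``max_steps=1`` returns the partial
    single-cleavage products instead. A molecule with no sugar substructure
    yields the empty set, so the operation is idempotent: running it on one
    of its own outputs returns nothing new.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    start = Chem.MolToSmiles(mol)

    if max_steps == 1:
        return _cleave_once(mol, sugar_library)

    aglycones: set[str] = set()
    seen: set[str] = set()
    frontier = {start}
    while frontier:
        current = frontier.pop()
        if current in seen:
            continue
        seen.add(current)
        products = _cleave_once(Chem.MolFromSmiles(current), sugar_library)
        if products:
            frontier |= products
        elif current != start:
            aglycones.add(current)
    return aglycones


def expand_compound_table(
    records: Sequence[CompoundRecord],
    sugar_library: Sequence[SugarPattern] = DEFAULT_SUGAR_LIBRARY,
) -> tuple[list[CompoundRecord], int]:
    """Append aglycone records for every glycoside in the table.

    Records without a structure pass through untouched. Aglycones shared by
    several parents are merged into one record whose ``parent_id`` lists all
    parents (``;``-separated). New records carry ``is_aglycone=True`` and a
    systematic id ``<first parent>_agl<k>``; the number of additions is
    returned alongside the expanded table.
    """
    expanded = list(records)
    by_canonical: dict[str, list[str]] = {}
    for record in records:
        if record.smiles is None:
            continue
        for aglycone in sorted(enumerate_aglycones(record.smiles, sugar_library)):
            by_canonical.setdefault(aglycone, []).append(record.compound_id)

    existing = set()
    for record in records:
        if record.smiles is not None:
            from rdkit import Chem

            mol = Chem.MolFromSmiles(record.smiles)
            if mol is not None:
                existing.add(Chem.MolToSmiles(mol))

    additions = 0
    for aglycone_smiles in sorted(by_canonical):
        parents = sorted(set(by_canonical[aglycone_smiles]))
        if aglycone_smiles in existing:
            continue  # aglycone already present as its own ingredient
        additions += 1
        expanded.append(
            CompoundRecord(
                compound_id=f"{parents[0]}_agl{additions}",
                name=f"aglycone of {'; '.join(parents)}",
                smiles=aglycone_smiles,
                is_aglycone=True,
                parent_id=";".join(parents),
            )
        )
    return expanded, additions
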