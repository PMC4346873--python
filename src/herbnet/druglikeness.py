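"""Tanimoto drug-likeness index over molecular descriptor vectors.

The drug-likeness (DL) of an ingredient is the continuous Tanimoto similarity

    T(A, B) = A.B / (|A|^2 + |B|^2 - A.B)

between the ingredient's descriptor vector A and the element-wise average B of
the descriptor vectors of a large reference set of known drugs ("average
drug" centroid). The original DL model was trained on 1533 proprietary Dragon
descriptors, which are not publicly enumerable; this module therefore accepts
*any* numeric descriptor vectors tagged with a schema id and ships one open
default schema computed with RDKit. Reproducing the original printed DL values
is explicitly not promised — published DL values are consumed as a property
column instead — but the index itself, its identities and its scale behaviour
are exactly those of the formula above.

No standardization is applied inside :func:`tanimoto_dl`; the formula is
applied to raw vectors. Optional z-scoring against the reference matrix is
available as an explicit preprocessing step (:func:`zscore`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DescriptorVector",
    "ReferenceCentroid",
    "SchemaMismatchError",
    "DESCRIPTOR_SCHEMAS",
    "tanimoto_dl",
    "reference_centroid",
    "compute_descriptors",
    "zscore",
    "save_centroid",
    "load_centroid",
]


class SchemaMismatchError(ValueError):
    """Two descriptor vectors from different schemas were compared."""


@dataclass(frozen=True)
class DescriptorVector:
    """An ordered real-valued descriptor vector tagged with its schema."""

    values: tuple[float, ...]
    schema_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("descriptor vector must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("descriptor vector entries must be finite")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class ReferenceCentroid:
    """Element-wise mean descriptor vector of a reference drug set."""

    vector: DescriptorVector
    n_source: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.n_source <= 0:
            raise ValueError("n_source must be positive")


def _check_comparable(a: DescriptorVector, b: DescriptorVector) -> None:
    if a.schema_id != b.schema_id:
        raise SchemaMismatchError(
            f"schema mismatch: {a.schema_id!r} vs {b.schema_id!r}"
        )
    if len(a.values) != len(b.values):
        raise SchemaMismatchError(
            f"length mismatch under schema {a.schema_id!r}: "
            f"{len(a.values)} vs {len(b.values)}"
        )


def tanimoto_dl(a: DescriptorVector, b: DescriptorVector) -> float:
    """Continuous Tanimoto coefficient A.B / (|A|^2 + |B|^2 - A.B).

    Symmetric in its arguments; equals 1.0 when A == B != 0 and 0.0 for
    orthogonal vectors. For vectors with nonnegative dot product the value
    lies in [0, 1]. Undefined (raises) when both vectors are all-zero.
    Note the index is scale sensitive: T(cA, A) != 1 for c != 1.
    """
    _check_comparable(a, b)
    va, vb = a.as_array(), b.as_array()
    dot = float(va @ vb)
    denom = float(va @ va) + float(vb @ vb) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined: both descriptor vectors are zero")
    return dot / denom


def reference_centroid(
    vectors: Sequence[DescriptorVector], provenance: str = ""
) -> ReferenceCentroid:
    """Element-wise arithmetic mean of a uniform-schema descriptor matrix."""
    if not vectors:
        raise ValueError("cannot build a centroid from an empty vector list")
    schema = vectors[0].schema_id
    for v in vectors[1:]:
        _check_comparable(vectors[0], v)
    matrix = np.vstack([v.as_array() for v in vectors])
    mean = matrix.mean(axis=0)
    return ReferenceCentroid(
        vector=DescriptorVector(tuple(mean), schema),
        n_source=len(vectors),
        provenance=provenance,
    )


def zscore(
    vector: DescriptorVector, reference: Sequence[DescriptorVector]
) -> DescriptorVector:
    """Standardize a vector against the column mean/sd of a reference matrix.

    Columns with zero variance are left centred but unscaled. This is an
    explicit, opt-in preprocessing step; :func:`tanimoto_dl` never scales.
    """
    if not reference:
        raise ValueError("empty reference matrix")
    for v in reference:
        _check_comparable(vector, v)
    matrix = np.vstack([v.as_array() for v in reference])
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    return DescriptorVector(tuple((vector.as_array() - mean) / sd), vector.schema_id)


# ---------------------------------------------------------------------------
# default open descriptor schema (RDKit)

def _schema_rdkit_constitutional():
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    return [
        ("mol_weight", Descriptors.MolWt),
        ("heavy_atoms", lambda m: float(m.GetNumHeavyAtoms())),
        ("logp", Crippen.MolLogP),
        ("h_donors", lambda m: float(Lipinski.NumHDonors(m))),
        ("h_acceptors", lambda m: float(Lipinski.NumHAcceptors(m))),
        ("rotatable_bonds", lambda m: float(Lipinski.NumRotatableBonds(m))),
        ("rings", lambda m: float(rdMolDescriptors.CalcNumRings(m))),
        ("aromatic_rings", lambda m: float(rdMolDescriptors.CalcNumAromaticRings(m))),
        ("tpsa", rdMolDescriptors.CalcTPSA),
        ("fraction_csp3", rdMolDescriptors.CalcFractionCSP3),
    ]


#: schema_id -> list of (descriptor name, function of an RDKit Mol)
DESCRIPTOR_SCHEMAS = {"rdkit-constitutional-v1": _schema_rdkit_constitutional}


def schema_names(schema_id: str) -> list[str]:
    """Descriptor names, in vector order, for a registered schema."""
    if schema_id not in DESCRIPTOR_SCHEMAS:
        raise KeyError(
            f"unknown schema {schema_id!r}; known: {sorted(DESCRIPTOR_SCHEMAS)}"
        )
    return [name for name, _ in DESCRIPTOR_SCHEMAS[schema_id]()]


def compute_descriptors(
    smiles: str, schema_id: str = "rdkit-constitutional-v1"
) -> DescriptorVector:
    """Compute the descriptor vector of a structure under a registered schema.

    The structure is canonicalized first so equivalent SMILES strings yield
    identical vectors. Raises ``ValueError`` carrying the input string when it
    cannot be parsed.
    """
    from rdkit import Chem

    if schema_id not in DESCRIPTOR_SCHEMAS:
        raise KeyError(
            f"unknown schema {schema_id!r}; known: {sorted(DESCRIPTOR_SCHEMAS)}"
        )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    values = tuple(float(fn(mol)) for _, fn in DESCRIPTOR_SCHEMAS[schema_id]())
    return DescriptorVector(values, schema_id)


# ---------------------------------------------------------------------------
# centroid persistence (one-row TSV with schema header)


def save_centroid(centroid: ReferenceCentroid, path) -> None:
    path = Path(path)
    names = "\t".join(f"d{i}" for i in range(len(centroid.vector.values)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema_id={centroid.vector.schema_id}\n")
        fh.write(f"# n_source={centroid.n_source}\n")
        fh.write(f"# provenance={centroid.provenance}\n")
        fh.write(names + "\n")
        fh.write("\t".join(repr(v) for v in centroid.vector.values) + "\n")


def load_centroid(path) -> ReferenceCentroid:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("# ") and "=" in line:
            key, _, value = line[2:].partition("=")
            meta[key] = value
        elif line.strip():
            rows.append(line)
    values = tuple(float(v) for v in rows[-1].split("\t"))
    return ReferenceCentroid(
        vector=DescriptorVector(values, meta["schema_id"]),
        n_source=int(meta["n_source"]),
        provenance=meta.get("provenance", ""),
    )
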