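"""Glycoside -> aglycone expansion with the built-in sugar library.

Colonic bacteria hydrolyze O-glycosidic bonds, so the absorbable species of
a herbal glycoside is its aglycone. Rutin (quercetin 3-O-rutinoside) loses
its disaccharide in two cleavage steps and yields quercetin.
"""

from rdkit import Chem

from herbnet import CompoundRecord, enumerate_aglycones, expand_compound_table

RUTIN = "CC1OC(OCC2OC(Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)C(O)C(O)C2O)C(O)C(O)C1O"
ASTRAGALIN = "OCC1OC(Oc2c(-c3ccc(O)cc3)oc3cc(O)cc(O)c3c2=O)C(O)C(O)C1O"

for name, smiles in [("rutin", RUTIN), ("astragalin", ASTRAGALIN), ("ethanol", "CCO")]:
    products = enumerate_aglycones(smiles)
    print(f"{name}: {sorted(products) or 'no glycosidic sugars found'}")

quercetin = Chem.CanonSmiles("O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12")
assert enumerate_aglycones(RUTIN) == {quercetin}

# expanding a compound table appends merged aglycone records
records = [
    CompoundRecord("G1", "rutin", smiles=RUTIN),
    CompoundRecord("G2", "astragalin", smiles=ASTRAGALIN),
]
expanded, added = expand_compound_table(records)
print(f"\ntable expansion added {added} aglycone record(s):")
for record in expanded[len(records):]:
    print(f"  {record.compound_id} ({record.name}): {record.smiles}")
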