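# herbnet

Network pharmacology for multi-compound herbal medicines. A herb is not one
drug: it is hundreds of ingredients acting on dozens of proteins at once, and
understanding its mechanism means (1) deciding which ingredients can actually
reach their targets, and (2) analyzing the topology of the resulting
compound–target, target–pathway and target–disease networks. `herbnet`
implements that workflow as a tested Python library with a thin command-line
layer, exercised end to end on the anti-inflammatory herb *Folium
Eriobotryae* (loquat leaf), whose published ingredient and target tables ship
as fixtures.

## What it computes

**ADME cascade screening.** Each ingredient carries three pharmacokinetic
screens: drug-likeness DL (the continuous Tanimoto index
T(A,B) = A·B / (|A|² + |B|² − A·B) between the compound's descriptor vector A
and the average descriptor vector B of known drugs), predicted oral
bioavailability OB (%), and log Caco-2 monolayer permeability. Survivors
satisfy DL ≥ 0.18, OB ≥ 30% and Caco-2 ≥ −0.4 (all inclusive). Declarative
**rescue rules** then re-admit pharmacologically justified failures: a
compound present at high content in the herb (content rescue), or one whose
gut metabolite is absorbable (metabolite rescue — the metabolite is admitted
too). Every decision lands in an audit trail.

**Glycoside expansion.** Colonic bacteria hydrolyze O-glycosides, so the
absorbable species is usually the aglycone. A SMARTS sugar library
(hexoses, deoxyhexoses, pentoses, hexuronic acids) marks the glycosidic
oxygen–anomeric carbon bond; cleavage iterates to fixpoint and aglycones are
deduplicated by canonical SMILES (rutin → quercetin).

**Interaction gating.** Predicted compound–target pairs must clear SVM ≥ 0.8
AND RF ≥ 0.7; literature-mined pairs pass unconditionally. A docking gate
keeps pairs with fitness strictly above 40. Targets are then subset by
disease annotation.

**Network topology.** Four bipartite graphs (drug–target, ingredient–target,
target–pathway, target–disease) with exact degree statistics (mean degree
2|E|/|V|, per-partition means |E|/|partition|), hub detection (degree above
the mean), cross-network target overlap, and Cytoscape-ready SIF/GraphML
export.

**Synthetic data.** A seeded generator draws property and score tables whose
marginal pass rates at the thresholds are set by config, so every stage is
testable at any scale without downloads.

## Worked example

```python
from herbnet import RescueRule, apply_rescues, load_fixture, run_cascade

table = load_fixture("table1")          # 29 published ingredients
result = run_cascade(table.records)     # DL -> OB -> Caco-2
final = apply_rescues(
    result, table.records,
    [RescueRule("content_rescue", content_min=7.0),
     RescueRule("metabolite_rescue", relaxed=("ob", "caco2"))],
    load_fixture("metabolite_map"),
)
print(result.stage_counts, len(final.final_set))
```

prints

```
{'dl': 28, 'ob': 27, 'caco2': 25} 29
```

— 28 of the 29 ingredients are drug-like, 27 also clear OB, 25 clear all
three thresholds, and the rescues (ursolic acid by content 7.57 mg/g;
chlorogenic acid and rutin via their absorbable metabolites caffeic acid and
quercetin) restore the full 29-compound active set. On the network side:

```python
from herbnet import build_bipartite, degree_summary, find_hubs, load_fixture

edges = [(r.compound_id, r.target_id) for r in load_fixture("it_edges").records]
net = build_bipartite(edges, "ingredients", "targets")
s = degree_summary(net)
print(f"{s.mean_degree_all:.2f} {s.mean_degree_right:.2f}", find_hubs(net, "left"))
```

```
3.04 1.91 [('M_05', 38), ('M_14', 15), ('M_04', 14), ('M_29', 5)]
```

— the 54-node, 82-edge ingredient–target network has mean degree 3.04
(targets 1.91), dominated by quercetin (degree 38), kaempferol, rutin and
caffeic acid. The `examples/` directory has one narrative script per
capability; the `herbnet` CLI exposes `screen`, `deglyco`, `targets`,
`network`, `simulate` and `run` subcommands over the same functions.

## Layout

- `src/herbnet/` — `io_model` (types and table I/O), `druglikeness`,
  `adme` (cascade + rescues), `deglyco`, `target_filter`, `networks`,
  `synthetic` (generator + fixtures), `pipeline`, `cli`
- `src/herbnet/data/` — packaged fixtures: the published ingredient and
  target tables, plus checksummed reconstruction fixtures for the network
  wirings (headers mark which files are reconstructions)
- `docs/methods.md` — models, parameters, numerical choices, limitations
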