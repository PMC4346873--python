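# Methods

## Scope and model

`herbnet` treats a herbal medicine as a set of candidate ingredients that
must pass pharmacokinetic plausibility screens before their protein targets
and network context are analyzed. The package deliberately consumes model
*outputs* — OB, Caco-2 and DL predictions, SVM/RF interaction scores,
docking fitness — as input columns. The upstream predictors (bioavailability
regression, chemogenomic models, docking engines) are prior art with
unpublished training data; re-deriving them is out of scope, and nothing in
this package should be read as an attempt to do so.

## ADME cascade

Three inclusive thresholds, applied in configurable order (the AND-set is
order independent; intermediate counts are not):

| stage | property | default threshold | rationale |
|---|---|---|---|
| dl | drug-likeness index, dimensionless in [0,1] | ≥ 0.18 | mean DL of the DrugBank-derived reference set |
| ob | oral bioavailability, % | ≥ 30 | conventional cut for "orally available" |
| caco2 | log apparent Caco-2 permeability | ≥ −0.4 | below −0.4 a compound is considered non-permeable |

A record missing the stage property is excluded with reason `missing`
(conservative screening — never a silent pass). Boundary semantics are
locked by tests: a value exactly at the threshold survives.

**Rescue rules.** Threshold screening is a model, and models miss real
actives. Two declarative exceptions are supported, both audited:

* `content_rescue` re-admits a failing compound whose measured herb content
  is ≥ `content_min` (mg/g dry herb). There is **no** biological default for
  `content_min`; the single published anchor is ursolic acid at 7.57 mg/g,
  and the shipped example configuration uses 7.0 mg/g to reproduce that
  rescue. High content can compensate a low fractional bioavailability in
  absolute terms.
* `metabolite_rescue` re-admits a failing parent when its mapped gut
  metabolite passes a relaxed criteria set, and admits the metabolite as
  well. The default relaxed set is {ob, caco2} with DL waived, modeled on
  caffeic acid (OB 51.08%, Caco-2 0.24, DL 0.05): absorption criteria are
  what matter for a species formed in the gut, while drug-likeness of the
  parent scaffold has already been vetted. Both parent and metabolite are
  admitted because the source tables keep the parents; `admit_parent=False`
  restricts to the metabolite. The parent→metabolite map covers *any*
  hydrolysis chemistry (the chlorogenic→caffeic mapping is an esterase
  reaction, so it belongs here and not in the glycosidase module).

On the packaged 29-row ingredient table the cascade yields 25 threshold
survivors and the three configured rescues re-admit 4 compounds (rutin,
ursolic acid, chlorogenic acid, caffeic acid) for a final set of 29. The
source text claims 26 compounds passed all three filters, but the printed
property values support only 25 — rutin (Caco-2 −1.91) sits among the
non-exceptional rows yet fails the stated threshold, and is simultaneously
described as an exceptional molecule. We follow the thresholds and document
the discrepancy rather than patching either number; the final 29 is reached
through rescues either way.

## Drug-likeness index

The DL index is the continuous Tanimoto coefficient
T(A,B) = A·B / (|A|² + |B|² − A·B) between a compound's descriptor vector
and a reference "average drug" centroid (element-wise arithmetic mean — the
source says "average" without qualification). Properties: T(A,A)=1 for
nonzero A; symmetric; within [0,1] when A·B ≥ 0; scale sensitive
(T(2A,A)=2/3), which is intentional — magnitude similarity is part of the
index.

The original model used 1533 proprietary Dragon descriptors that cannot be
enumerated. The operation therefore accepts any uniform-schema numeric
vectors, and the package ships one open 10-descriptor RDKit schema
(`rdkit-constitutional-v1`: MW, heavy atoms, logP, H-bond donors/acceptors,
rotatable bonds, ring and aromatic ring counts, TPSA, sp³ carbon fraction).
Reproducing published DL values (e.g. 0.76 for oleanolic acid) is explicitly
not promised — published DL values are consumed from the property table.
Whether the original work standardized descriptors before the formula is
unstated; `tanimoto_dl` itself never scales (mirroring the formula
literally) and a z-score preprocessing step is provided as an explicit
opt-in. Neither mode is claimed to match the original.

## Deglycosylation

Emulates glycosidase hydrolysis as a substructure rewrite. Each sugar
pattern is a SMARTS with two mapped atoms: the exocyclic glycosidic oxygen
(stays on the aglycone, becoming a hydroxyl through implicit-hydrogen
bookkeeping) and the anomeric ring carbon (leaves with the sugar). Design
choices:

* Library: hexose, deoxyhexose, pentose, hexuronic acid ring patterns cover
  the common herbal sugars (glucose/galactose, rhamnose/fucose,
  arabinose/xylose, glucuronic acid); disaccharides such as rutinose need no
  dedicated pattern because hydrolysis iterates to fixpoint, stripping one
  sugar per step. The library is extensible from a plain-text SMARTS file.
* Only O-glycosides are cleaved. C-glycosides resist glycosidases and never
  match; glycosyl esters are excluded by the `[#6;!$([#6]=O)]` attachment
  atom (ester hydrolysis is esterase chemistry, handled by the metabolite
  map).
* Anomeric stereochemistry is not specified in the patterns (both anomers
  match); stereocenters on the aglycone side are preserved.
* Full (fixpoint) hydrolysis is the default since colonic flora eventually
  strip all sugars; `max_steps=1` exposes partial hydrolysis products.

Invariants under test: every aglycone has strictly fewer heavy atoms than
its parent; enumeration of an aglycone returns the empty set (idempotence);
products are independent of the input SMILES form. Verified chemistry:
rutin → quercetin, kaempferol 3-O-glucoside → kaempferol.

## Interaction gating

Prediction gate: predicted records need SVM ≥ 0.8 AND RF ≥ 0.7 (inclusive,
per the stated criteria); literature records are experimentally supported
and pass unconditionally. Docking gate: fitness strictly greater than 40
("greater than", hence strict; `dock_strict=False` for inclusive). Whether
literature pairs should also be docked is genuinely ambiguous in the source
(docking is described as validating "these predicted" interactions);
`dock_literature` defaults to False (literature pairs skip docking) and is
documented rather than claimed. Disease matching is exact-string against
the annotation table — synonym/ontology expansion is the curator's job, not
the filter's.

## Networks

All four networks are simple bipartite graphs. Mean degree is 2|E|/|V| over
all nodes — the only reading under which the reference values (3.04 overall,
1.91 for targets, with 54 nodes and 82 edges) arise — with per-partition
means available. The hub rule is degree strictly greater than the all-node
mean; "much larger than average" is vague in the source, so the strict rule
is the package default (with an optional multiplier), documented rather than
claimed as the original rule. Degrees are integers; means are computed
exactly and rounded only at presentation (2 decimals). Node ids are
namespaced `role:id` in exports so a gene symbol can appear in different
partitions across merged files; SIF and GraphML exports round-trip node and
edge sets exactly.

## Synthetic generator

The generator emulates the *statistical shape* of a screening campaign, not
its chemistry: property values are real numbers with controlled pass rates,
compounds carry no structures, and scores are independent of properties.
Pass-rate parameterization decides each record's pass/fail label first
(binomially, or exactly `round(p·n)` with `exact=True`) and then draws the
value from the base distribution conditioned on the labelled side of the
threshold by inverse-CDF sampling, so requested marginal rates hold at any
n. Base distributions: OB truncated normal on [0,100] (mean 30, sd 20 — a
broad, realistic spread for herbal ingredient OB predictions), Caco-2 normal
(mean −0.4, sd 0.8), DL Beta(1.2, 2.5) (right-skewed, most natural products
weakly drug-like). Default pass rates are the published funnel fractions
134/389, 61/134, 26/61; properties are drawn independently, so conditional
and marginal rates coincide. All randomness flows through one mandatory
seed.

What passing synthetic tests does **not** show: correlated properties (real
DL and Caco-2 co-vary with lipophilicity), structure-property coherence, or
realistic score-edge dependence. Those claims are only exercised on the
packaged real tables.

## Fixtures

`table1` (29 ingredients with printed OB/Caco-2/DL, content, bioactivity
annotations) and `table2` (43 targets with gene symbols and verbatim UniProt
accessions, six flagged as shared with approved drugs) are transcriptions of
published tables. The network wirings (ingredient-target, drug-target,
pathway and disease memberships) were never published beyond summary
statistics; the packaged edge fixtures are **reconstructions**, generated by
a deterministic greedy realization of every printed constraint (82 I–T edges;
compound degrees 38/15/14/5 for the four named hubs; target degrees COX2 6,
ALOX5/PPARG/TNF/RELA 4, all 43 ≥ 1; 176 D–T edges with NR3C1 32, COX2 28,
COX1 24; the six bold shared targets; pathway degrees influenza A 16,
toll-like 14, NF-κB 12, MAPK 10 with BCHE unmapped) with the remaining
wiring filled in id order. Each file's header marks it as a reconstruction,
and all fixtures are sha256-locked: editing any transcription fails the
suite. Interaction scores in the I–T fixture are synthesized above all gates
by a fixed arithmetic pattern so the gating funnel retains the full edge
set.

## Numerical and engineering choices

* Numeric fields parse at full float precision (unicode minus tolerated);
  reports print at 2 decimals. Ids, not names, are join keys; Greek names
  are preserved verbatim.
* Malformed data rows are quarantined with a reason, never dropped silently
  (`rows in = parsed + quarantined` is a tested invariant); structural
  faults — missing columns, duplicate keys — abort.
* Problem sizes in the test suite: pass-rate recovery at n = 5000, funnel
  shape at n = 2000, 200 random networks for the handshake/hub-oracle
  property checks — large enough for 3-binomial-SE assertions to be
  discriminating, small enough that the whole suite runs in seconds.
* Pipeline exit codes: 0 success, 2 validation error, 3 stage error. The
  run manifest records config snapshot, input sha256s, version, seed and
  stage timings; artifacts are byte-identical across reruns (timings live
  only in the manifest).

## Known limitations

* The full published funnels (389→134→61→26 compounds; 232→53→43 targets)
  depend on unpublished appendix tables and score files and cannot be
  recomputed; they are emulated statistically instead.
* The DL schema is open but small; absolute DL values are not comparable to
  those from the 1533-descriptor original.
* Deglycosylation is rule-based: no kinetics, no regioselective enzymes, no
  partial-hydrolysis product distribution.
* Reconstruction fixtures satisfy every printed constraint but are not the
  original wirings; conclusions that depend on unprinted edges (e.g. which
  minor compound hits which minor target) are not supported.
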