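"""Degree topology of the ingredient-target and drug-target networks.

Builds both bipartite graphs from the packaged edge fixtures, prints mean
degrees, hub compounds (degree above the all-node mean) and the targets the
herb shares with approved anti-inflammatory drugs, then maps targets onto
the inflammation pathway table.
"""

from herbnet import (
    build_bipartite,
    degree_summary,
    find_hubs,
    load_fixture,
    map_targets_to_pathways,
    shared_targets,
)

it_edges = [(r.compound_id, r.target_id) for r in load_fixture("it_edges").records]
it_net = build_bipartite(it_edges, "ingredients", "targets", name="ingredient-target")
dt_net = build_bipartite(load_fixture("dt_edges"), "drugs", "targets", name="drug-target")

summary = degree_summary(it_net)
print(
    f"I-T network: {len(it_net.left) + len(it_net.right)} nodes, "
    f"{len(it_net.edges)} edges, mean degree {summary.mean_degree_all:.2f} "
    f"(targets {summary.mean_degree_right:.2f})"
)
print("hub ingredients (degree > mean):")
for node, degree in find_hubs(it_net, "left"):
    print(f"  {node}: {degree}")

print("\ntargets shared with approved drugs:", ", ".join(shared_targets(dt_net, it_net)))

edges, unmapped = map_targets_to_pathways(sorted(it_net.right), load_fixture("pathways"))
print(f"\ntarget-pathway edges: {len(edges)}; unmapped targets: {unmapped}")
# quercetin (M_05, degree 38) dominates the I-T network; BCHE maps to no
# inflammation pathway.
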