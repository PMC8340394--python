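"""Resolve a soft polytomy while reconciling.

A trifurcating gene vertex carries three genes whose species placements
favour one grouping and whose syntenic regions favour another.  The joint
solver considers every binary resolution and reports the cheapest overall,
together with the resolved tree it used.
"""

from dtlor import EventCosts, Instance, LeafAssociation, parse_newick, solve_nonbinary
from dtlor.model import event_counts
from dtlor.trees import write_newick

species = parse_newick("((s1,s2)x,s3)r;")
genes = parse_newick("(g1,g2,g3)v;")  # unknown divergence order
assoc = LeafAssociation(
    phi={"g1": "s1", "g2": "s2", "g3": "s3"},
    gamma={"g1": 1, "g2": 2, "g3": 2},
)
instance = Instance(species, genes, assoc, EventCosts(1, 1, 1, 2, 2))

result = solve_nonbinary(instance)
print(f"optimal cost: {result.opt}")
print(f"resolved gene tree: {write_newick(result.resolved_tree)}")
print(f"event counts: {event_counts(result.reconciliation.events())}")

# Grouping (g1,g2) mirrors the species tree (free speciations) but needs a
# rearrangement; grouping (g2,g3) shares a region but fights the species
# topology.  The DP prices both at once instead of fixing either first.
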