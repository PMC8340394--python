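"""Reconcile a small binary gene tree against a species tree.

Three genes map one-to-one onto three species; two share a syntenic region
and one sits in its own.  The solver weighs a single origin plus one
rearrangement against two independent origins.
"""

from dtlor import EventCosts, Instance, LeafAssociation, parse_newick, reconcile
from dtlor.model import event_counts

species = parse_newick("((a,b)x,c)r;")
genes = parse_newick("((ga,gb)u,gc)v;")
assoc = LeafAssociation(
    phi={"ga": "a", "gb": "b", "gc": "c"},
    gamma={"ga": 1, "gb": 1, "gc": 2},
)
instance = Instance(species, genes, assoc, EventCosts(1, 1, 1, 2, 2))

result = reconcile(instance, count=True)
rec = result.reconciliation

print(f"optimal cost: {result.opt}")
print(f"co-optimal reconciliations: {result.mpr_count}")
print(f"event counts: {event_counts(rec.events())}")
for g in genes.postorder:
    s = rec.species_map[g] or "N"
    lab = rec.synteny_map[g] or "*"
    print(f"  {g}: species {s}, region {lab}")

# The optimum (4) is reached three ways: one origin with the odd leaf
# rearranged (in either direction), or two separate origins.  The traced
# solution is the deterministic first of these.
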