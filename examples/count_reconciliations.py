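"""Count co-optimal reconciliations exactly.

Maximum parsimony often admits many optima; downstream conclusions should
know how many.  The count is exact (arbitrary precision) and verified here
against brute-force enumeration of every valid mapping pair.
"""

from dtlor import EventCosts, Instance, LeafAssociation, count_mprs, parse_newick, solve
from dtlor.oracle import brute_force_opt

species = parse_newick("((a,b)x,c)r;")
genes = parse_newick("((ga,gb)u,gc)v;")
assoc = LeafAssociation(
    phi={"ga": "a", "gb": "b", "gc": "c"},
    gamma={"ga": 1, "gb": 1, "gc": 2},
)
instance = Instance(species, genes, assoc, EventCosts(1, 1, 1, 2, 2))

opt, tables = solve(instance)
count = count_mprs(instance, tables)
oracle = brute_force_opt(instance, include_pairs=True)

print(f"optimal cost: {opt}  (brute force: {oracle.cost})")
print(f"distinct optima: {count}  (brute force: {oracle.count})")
for i, (phi_map, gamma_map) in enumerate(oracle.pairs, 1):
    print(f"  optimum {i}: root region {gamma_map['v'] or '*'}, "
          f"root species {phi_map['v'] or 'N'}")

# Three optima: the root labeled with either region under one origin, or
# the root left outside the species tree with two origins below it.
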