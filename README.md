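# dtlor

Maximum parsimony reconciliation of a rooted gene tree against a rooted
species tree under the **DTLOR** model: **D**uplication, **T**ransfer,
**L**oss, **O**rigin and **R**earrangement.

## Why this model

Standard duplication–transfer–loss (DTL) reconciliation assumes every gene
lineage lives inside the sampled species tree. In clades of closely related
microbes that assumption routinely fails: gene families enter the clade by
horizontal transfer from unsampled lineages, and genes move between
*syntenic regions* of the genome (integer labels summarising shared
core-gene context — the signature used to delimit genomic islands). DTLOR
extends DTL with two events:

* an **origin** — a gene lineage enters the sampled species tree from
  outside; vertices still evolving outside map to the special location *N*
  and carry the unknown region `*`;
* a **rearrangement** — a gene edge changes its syntenic region within the
  tree.

A reconciliation is a pair of mappings (Φ, Γ): Φ sends gene vertices to
species vertices or *N*, Γ sends them to a region in *L* or `*`, with
Φ(g)=N ⇔ Γ(g)=`*`. Each internal vertex mapped inside the tree induces a
speciation (free), duplication (cost **D**) or transfer (**T**); passing
unobserved through a species vertex costs a loss (**L**); each origin costs
**O** and each region change **R**. The maximum parsimony reconciliation
(MPR) minimises the weighted event total.

For **binary** gene trees, within each origin subtree the species map and
the region labeling are independent, so two small dynamic programs —
`C(e_g, e_s)` over gene-edge × species-edge pairs (with Best-Entry /
Best-Transfer tables for transfer landings) and `syn(g, ℓ)` over vertices ×
regions — combine through an Origin/Null recursion in O(|G||S| + |G||L|)
time. For **multifurcating** gene trees the two criteria interact; a joint
DP `C(e_g, e_s, ℓ)` evaluated over every binary resolution of each
polytomy solves the problem exactly in O(f(k)·k·|G||S||L|) time, where
f(k) = (2k−3)!! resolutions for the largest vertex degree k.

The package also provides a deterministic traceback, an exact count of
co-optimal (Φ, Γ) pairs (binary case), brute-force oracles that certify the
dynamic programs on small instances, and seeded generators including a
forward event simulator.

## Worked example

Three genes map one-to-one onto three species; two share syntenic region 1,
one sits in region 2 (`examples/reconcile_binary.py`):

```text
optimal cost: 4
co-optimal reconciliations: 3
event counts: {'duplication': 0, 'transfer': 0, 'loss': 0, 'origin': 2, 'rearrangement': 0}
  ga: species a, region 1
  gb: species b, region 1
  u: species x, region 1
  gc: species c, region 2
  v: species N, region *
```

With costs (D,T,L,O,R) = (1,1,1,2,2), one origin plus one rearrangement
ties with two independent origins at cost 4, and there are exactly three
optima (the traced one keeps the root outside the species tree and starts
two origin subtrees). The same instance is solvable from the shell:

```sh
dtlor reconcile --species S.nwk --gene G.nwk --map map.tsv --synteny syn.tsv \
      -D 1 -T 1 -L 1 -O 2 -R 2 --count --out rec.json
```

`examples/` holds one short script per capability: binary reconciliation,
polytomy resolution, exact MPR counting, and forward simulation with the
parsimony bound. `docs/methods.md` describes the algorithms, defaults and
numerical conventions.

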