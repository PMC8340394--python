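# Methods

## Model

A problem instance is a 10-tuple: a binary rooted species tree *S*, a
rooted gene tree *G* (binary, or multifurcating for the joint solver), a
finite set *L* of syntenic regions (positive integers), a tip map
φ: Le(G) → Le(S), a surjective tip labeling γ: Le(G) → L, and five
nonnegative event costs **D**, **T**, **L**, **O**, **R**. Both trees are
undated; branch lengths in input newick are ignored. Every tree carries an
implicit *handle* edge above its root, and each vertex is identified with
its incoming edge (the root's being the handle), so tables indexed by
"edges" are indexed by vertices.

A reconciliation is a pair (Φ, Γ) extending (φ, γ) to all gene vertices.
Φ maps into V(S) ∪ {N}; Γ into L ∪ {\*}; Φ(g)=N iff Γ(g)=\*. A vertex with
an actual region cannot have a `*` child (once a family is inside the
sampled tree it stays), and a vertex mapped inside the tree must have both
children inside, neither mapped to an ancestor of its own image, and at
least one mapped at or below it. Induced events:

* **speciation** (free): children split across the two subtrees below Φ(g);
* **duplication** (D): both children at or below Φ(g), not a speciation;
* **transfer** (T): one child at or below Φ(g), the other incomparable;
* **loss** (L): a non-root vertex whose parent maps strictly above it loses
  at every vertex it passes on the way down, excluding its own image, and
  excluding the parent's image exactly when the parent speciates (after a
  duplication or transfer the lineage still has to survive that vertex's
  subsequent speciation, so the top endpoint counts);
* **origin** (O): a vertex with an actual region whose parent is `*` (or
  the root with an actual region);
* **rearrangement** (R): a gene edge whose two actual region labels differ.

Entry from outside induces no losses: there is no path from N.

## Binary solver

Inside an origin subtree all vertices are inside the tree with actual
regions, and the species map and the labeling are independent, so two
decoupled DPs suffice.

**Species DP.** `C(e_g, e_s)` is the optimal cost of the subtree G(g) with
the gene edge *placed* on species edge `e_s`, filled with gene edges outer
/ species edges inner, both postorder. At two leaves it is 0 iff φ agrees;
otherwise it is the minimum of speciation (children edges on the two child
edges, both pairings), loss (**L** plus continuing onto either child
edge), duplication (**D** plus both children placed here) and transfer
(**T** plus one child here and the other on the cheapest edge incomparable
to `e_s`). Incomparable minima come from `Best-Entry` (cheapest placement
within each species subtree, bottom-up) and `Best-Transfer` (preorder:
infinite at the handle, then min of the parent's value and the sibling's
Best-Entry). The handle is a legal placement — a gene may map to the
species root — but no edge is incomparable to it, so it is never a
transfer target. `C(g)` minimises over all species edges and is always
finite.

Alongside `C` the implementation fills a *terminates* table `term(e_g,
e_s)`: the optimal cost with Φ(g)=s exactly (no loss alternative). The two
agree after minimising over any species subtree, so every published
recurrence is reproduced verbatim on values, but `term` makes DP traces
correspond one-to-one with species maps. That distinction is invisible
when all costs are positive and essential when some are zero (allowed
here): with L=0 a loss chain below a transfer landing produces the same Φ
as landing lower directly, and with D=2L=0 a duplication cell can cover a
placement that is really a speciation. Counting therefore uses `term` for
origin roots and transfer landings, and the duplication cell decomposes
each child's placement into {terminate here / enter left subtree / enter
right subtree} and excludes the left/right pair, which is the speciation
pattern.

**Synteny DP.** `syn(g, ℓ)` is the optimal rearrangement cost of labeling
G(g) with root label ℓ: 0/∞ at leaves; at internal vertices each child
independently keeps ℓ or pays **R** for its own best label. The unknown
region never enters this table.

**Combination.** `Origin(g) = O + C(g) + syn(g)` prices G(g) as one origin
subtree. `Null(g)` (g outside: ∞ at leaves, otherwise each child
independently chooses min{Null, Origin}) locates the origin events;
`Opt = min(Null(root), Origin(root))`. A single-leaf gene tree has
`Opt = O`: the leaf is its own origin.

**Traceback** is deterministic: Null before Origin; at a cell speciation,
then loss, then duplication, then transfer; first species edge in
postorder; smallest region label; a child keeps its parent's label on
ties. The traced (Φ, Γ) is re-validated and re-scored through the event
inference path; disagreement with Opt raises `AssertionError` (a bug trap,
not a user error).

**Counting** multiplies independent factors: per origin subtree, the
number of optimal species maps (sum of `term` counts over edges achieving
`C(g)`) times the number of optimal labelings; per outside vertex, the
product over children of their tie-aware choice counts. Loss placements
are determined by Φ, so no double counting; integers are exact at any
size.

## Non-binary solver

With soft polytomies the species-best and labeling-best resolutions can
differ, so the DP is joint: `C(e_g, e_s, ℓ)` adds the root's region to the
state, and every child term chooses between keeping ℓ and paying **R** for
the child's free minimum (`C(e_child, e_s, L)`). Best-Entry/Best-Transfer
are region-indexed with the same structure as before.

Each multifurcation g with children g₁..g_k is expanded into all
(2k−3)!! binary resolutions, enumerated duplicate-free by inserting each
successive child on every edge (including above the root) of every smaller
tree. Within a resolution *H*, leaf edges inherit the children's already
*merged* tables, so the work is additive across vertices, not
multiplicative. The merged `C(e_g, ·, ·)` is the cellwise minimum over
resolutions.

`Null` also runs inside each resolution: when g stays outside, an origin
may occur at a vertex internal to *H*, grouping several original children
under a single **O** (two children that jointly mirror a species cherry
cost one origin, not two). `Null(g)` is therefore the minimum over
resolutions of the within-resolution recursion, with
`Origin(h) = O + min C(e_h, ·, ·)` available at resolution-internal
vertices. The per-cell winning resolution is recorded, and traceback
reconstructs one optimal fully resolved binary gene tree plus a
reconciliation on it, validated and re-scored as in the binary case.
Exact counting is not offered for multifurcating inputs: when two
reconciliations on different resolutions count as distinct is not well
defined, so `count_mprs` is restricted to binary trees.

The arity cap defaults to 8 (10 395 resolutions per vertex); larger
multifurcations raise an error rather than silently truncating.

## Numerical conventions

* Costs are exact rationals (`fractions.Fraction`); all DP comparisons are
  exact, and integer-cost instances never touch floating point except for
  the saturating sentinel ∞ (`float("inf")`), which absorbs addition and
  behaves correctly under `min`.
* Zero costs are accepted (the strict-positivity of costs is relaxed so
  that reductions such as R=0 are expressible); they are degenerate in
  that optimum sets can be very large, which the counting machinery
  handles exactly.
* Determinism: child order is preserved from input and used only for
  iteration and tie-breaking, never for semantics; identical inputs give
  byte-identical JSON reports.

## Oracles and generators

`dtlor.oracle` holds brute-force references used only in tests: exhaustive
enumeration of valid Φ (postorder assignment with pruning) and Γ, grouped
by their shared outside set so per-set minima and counts combine; and
exhaustive enumeration of complete resolutions for the non-binary case.
Guards (13 gene vertices, 9 species vertices, 10⁴ resolutions) are hard
errors.

`dtlor.synthgen` generates seeded random instances (random sequential leaf
attachment; random φ; surjective random γ; optional edge contraction up to
a max arity) and forward-simulated histories. Defaults — 5 species leaves,
5 gene leaves, 2 regions, per-vertex event probabilities 0.1 — reflect the
small, closely related clades the model targets. Two deliberate
simplifications in the simulator: losses are pass-through at speciations
(the lineage continues into exactly one child), so no lineage goes fully
extinct and the recorded truth is always a valid reconciliation (a
transfer whose resident copy later died out has no valid annotation under
the placement constraints); and region labels that fail to survive to any
leaf are repaired to the first descendant leaf's region so the truth maps
into L. Consequently the simulator does not emulate complete gene-family
extinction in a lineage, gene conversion, or replacement transfer;
passing its tests shows the parsimony bound and recovery on clean
histories, not performance on such data.

## Problem sizes in the checks

The randomized certification runs use species trees of 2–5 leaves, gene
trees of 2–6 leaves, up to 3 regions and integer costs 0–3 — small enough
for the brute-force oracles, large enough to hit every event type and
every tie class. The scaling check times the binary solver at 16–200
leaves per tree and asserts only a trend (log-log slope against
|G||S| + |G||L| near 1), never an absolute time.

## Known limitations

* Time-consistency of the implied event ordering is not checked; an MPR
  may be time-inconsistent (detecting that is a separate problem, and
  requiring consistency makes the optimisation NP-hard).
* Duplications are modeled as tandem/proximal: a duplication alone does
  not change region; a dispersed duplication is a duplication plus a
  rearrangement.
* No enumeration of all MPRs, support values, or representative selection;
  no unrooted input or rooting search; no use of branch lengths.
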