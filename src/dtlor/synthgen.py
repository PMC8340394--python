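"""Seeded generators of random instances and forward-simulated histories.

The forward simulator is a testing aid, not a calibrated evolutionary
model: events are per-vertex Bernoulli draws, not a continuous-time
process.  A single gene lineage enters the species tree at a configurable
edge (an origin event) and evolves towards the tips; at each species
vertex it may duplicate, jump to an incomparable edge (transfer), pass
through only one child (a loss on the other side), or speciate.  Losses
are pass-through by construction — a lineage never goes completely
extinct — so the recorded true history is always expressible as a valid
reconciliation and its cost is an upper bound on the parsimony optimum.

Syntenic regions are assigned top-down with a per-edge rearrangement
probability; labels that do not survive to any leaf are repaired to the
region of the first descendant leaf so that the true labeling stays within
the leaf-observed region set L.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from fractions import Fraction

from .exceptions import InputError
from .model import EventCosts, EventRecord, Instance, Reconciliation, score_reconciliation
from .trees import LeafAssociation, RootedTree

__all__ = ["GeneratorConfig", "SimulatedHistory", "random_instance", "simulate_history",
           "random_binary_tree"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the generators; identical configs give identical output.

    Defaults target the regime the solvers are exercised in: small trees of
    closely related species, a couple of syntenic regions, and modest
    per-vertex event probabilities (a tenth each), which yield histories
    with a handful of duplications, transfers and losses.
    """

    seed: int = 0
    species_leaves: int = 5
    gene_leaves: int = 5
    max_arity: int = 2
    contract_prob: float = 0.4
    synteny_labels: int = 2
    p_dup: float = 0.1
    p_transfer: float = 0.1
    p_loss: float = 0.1
    p_rearr: float = 0.1
    origin_at_root: bool = True
    costs: EventCosts = field(default_factory=EventCosts)
    max_gene_vertices: int = 512

    def __post_init__(self) -> None:
        for p in (self.p_dup, self.p_transfer, self.p_loss, self.p_rearr,
                  self.contract_prob):
            if not 0.0 <= p <= 1.0:
                raise InputError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedHistory:
    """A forward-simulated history with its ground-truth reconciliation."""

    instance: Instance
    species_map: dict[str, str]
    synteny_map: dict[str, int]
    events: list[EventRecord]
    true_cost: Fraction

    @property
    def reconciliation(self) -> Reconciliation:
        return Reconciliation(
            self.instance.gene_tree,
            self.instance.species_tree,
            dict(self.species_map),
            dict(self.synteny_map),
        )


def random_binary_tree(rng: random.Random, leaf_names, internal_prefix: str) -> RootedTree:
    """Uniform-ish random topology by sequential random leaf attachment."""
    leaf_names = list(leaf_names)
    if not leaf_names:
        raise InputError("need at least one leaf")
    counter = itertools.count()
    tree = leaf_names[0]
    for leaf in leaf_names[1:]:
        # choose a uniformly random edge (subtree occurrence incl. the handle)
        edges: list[tuple] = []

        def collect(sub, path):
            edges.append((sub, path))
            if isinstance(sub, tuple):
                collect(sub[0], path + (0,))
                collect(sub[1], path + (1,))

        collect(tree, ())
        _, path = edges[rng.randrange(len(edges))]

        def attach(sub, path):
            if not path:
                return (sub, leaf)
            a, b = sub
            if path[0] == 0:
                return (attach(a, path[1:]), b)
            return (a, attach(b, path[1:]))

        tree = attach(tree, path)

    children: dict[str, tuple[str, ...]] = {}

    def name(sub) -> str:
        if isinstance(sub, str):
            return sub
        nm = f"{internal_prefix}{next(counter)}"
        children[nm] = (name(sub[0]), name(sub[1]))
        return nm

    root = name(tree)
    return RootedTree(root, children)


def _contract_edges(tree: RootedTree, rng: random.Random, max_arity: int,
                    prob: float) -> RootedTree:
    """Randomly contract internal edges to create soft polytomies."""
    children = {v: list(tree.children(v)) for v in tree.postorder}
    for v in tree.postorder:
        p = tree.parent(v)
        if p is None or tree.is_leaf(v) or v not in children:
            continue
        if len(children[p]) - 1 + len(children[v]) > max_arity:
            continue
        if rng.random() < prob:
            i = children[p].index(v)
            children[p][i: i + 1] = children[v]
            del children[v]
    return RootedTree(tree.root, {v: tuple(k) for v, k in children.items()})


def random_instance(config: GeneratorConfig) -> Instance:
    """A random instance: random topologies, random phi, random surjective gamma."""
    rng = random.Random(config.seed)
    if config.synteny_labels > config.gene_leaves:
        raise InputError(
            "cannot draw a surjective synteny map: more labels than gene leaves"
        )
    S = random_binary_tree(
        rng, [f"s{i}" for i in range(config.species_leaves)], "S"
    )
    G = random_binary_tree(
        rng, [f"g{i}" for i in range(config.gene_leaves)], "G"
    )
    if config.max_arity > 2:
        G = _contract_edges(G, rng, config.max_arity, config.contract_prob)
    sp_leaves = list(S.leaves)
    phi = {g: rng.choice(sp_leaves) for g in G.leaves}
    gene_leaves = list(G.leaves)
    pinned = rng.sample(gene_leaves, config.synteny_labels)
    gamma = {}
    for lab, g in enumerate(pinned, start=1):
        gamma[g] = lab
    for g in gene_leaves:
        if g not in gamma:
            gamma[g] = rng.randint(1, config.synteny_labels)
    assoc = LeafAssociation(phi=phi, gamma=gamma)
    return Instance(S, G, assoc, config.costs)


def simulate_history(config: GeneratorConfig) -> SimulatedHistory:
    """Forward-simulate one gene family down a random species tree."""
    rng = random.Random(config.seed)
    S = random_binary_tree(
        rng, [f"s{i}" for i in range(config.species_leaves)], "S"
    )
    made = [0]
    children: dict[str, tuple[str, ...]] = {}
    species_map: dict[str, str] = {}

    def fresh() -> str:
        made[0] += 1
        return f"g{made[0] - 1}"

    def incomparable_edges(s: str) -> list[str]:
        return [t for t in S.postorder if not S.are_comparable(s, t)]

    def evolve(s: str) -> str:
        """A lineage placed on edge e_s; returns the gene vertex it becomes."""
        budget_ok = made[0] < config.max_gene_vertices
        if budget_ok and rng.random() < config.p_dup:
            v = fresh()
            species_map[v] = s
            children[v] = (evolve(s), evolve(s))
            return v
        targets = incomparable_edges(s)
        if budget_ok and targets and rng.random() < config.p_transfer:
            v = fresh()
            species_map[v] = s
            children[v] = (evolve(s), evolve(rng.choice(targets)))
            return v
        if S.is_leaf(s):
            v = fresh()
            species_map[v] = s
            return v
        s1, s2 = S.children(s)
        if rng.random() < config.p_loss:
            # pass-through: the lineage survives in exactly one child
            return evolve(rng.choice((s1, s2)))
        v = fresh()
        species_map[v] = s
        children[v] = (evolve(s1), evolve(s2))
        return v

    origin_edge = S.root if config.origin_at_root else rng.choice(S.postorder)
    root = evolve(origin_edge)
    G = RootedTree(root, children)

    # synteny labels, top-down, fresh label on each rearranged edge
    label_counter = itertools.count(1)
    synteny_map: dict[str, int] = {root: next(label_counter)}
    for v in reversed(G.postorder):
        for c in G.children(v):
            if rng.random() < config.p_rearr:
                synteny_map[c] = next(label_counter)
            else:
                synteny_map[c] = synteny_map[v]
    leaf_labels = {synteny_map[g] for g in G.leaves}
    first_leaf_below: dict[str, str] = {}
    for v in G.postorder:
        first_leaf_below[v] = v if G.is_leaf(v) else first_leaf_below[G.children(v)[0]]
    for v in G.postorder:
        if synteny_map[v] not in leaf_labels:
            synteny_map[v] = synteny_map[first_leaf_below[v]]

    phi = {g: species_map[g] for g in G.leaves}
    gamma = {g: synteny_map[g] for g in G.leaves}
    assoc = LeafAssociation(phi=phi, gamma=gamma)
    instance = Instance(S, G, assoc, config.costs)
    rec = Reconciliation(G, S, dict(species_map), dict(synteny_map))
    events = rec.events()
    true_cost = score_reconciliation(rec, config.costs)
    return SimulatedHistory(
        instance=instance,
        species_map=species_map,
        synteny_map=synteny_map,
        events=events,
        true_cost=true_cost,
    )
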