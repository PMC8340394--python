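"""DTLOR event semantics: instances, reconciliations, event inference, scoring.

A reconciliation is a pair of mappings ``(Phi, Gamma)``:

* ``Phi`` sends each gene-tree vertex to a species-tree vertex or to the
  special location *N* (outside the sampled species tree), represented here
  by ``None``;
* ``Gamma`` sends each gene-tree vertex to an actual syntenic region (a
  positive integer) or to the unknown region ``*``, also ``None``.

The two are coupled: ``Phi(g) is None`` iff ``Gamma(g) is None``.  From a
valid pair the event list — speciations, duplications, transfers, losses,
origins, rearrangements — is a pure function, implemented here and used both
to score solver output and as the independent check that dynamic-programming
results mean what they claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

from .exceptions import InputError
from .trees import LeafAssociation, RootedTree

__all__ = [
    "EventCosts",
    "Instance",
    "EventRecord",
    "Reconciliation",
    "classify_vertex_event",
    "infer_losses",
    "infer_or_events",
    "infer_events",
    "score_reconciliation",
    "validate_reconciliation",
    "event_counts",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
TRANSFER = "transfer"
LOSS = "loss"
ORIGIN = "origin"
REARRANGEMENT = "rearrangement"


def _as_cost(x) -> Fraction:
    c = Fraction(x)
    if c < 0:
        raise InputError(f"event costs must be nonnegative, got {x!r}")
    return c


@dataclass(frozen=True)
class EventCosts:
    """The five per-event costs D, T, L, O, R (speciation is free).

    Costs are kept as exact rationals so that optimal values compare
    exactly.  Zero costs are accepted (useful for reductions) but are
    degenerate: they can make the number of co-optimal reconciliations very
    large.
    """

    duplication: Fraction = Fraction(1)
    transfer: Fraction = Fraction(1)
    loss: Fraction = Fraction(1)
    origin: Fraction = Fraction(2)
    rearrangement: Fraction = Fraction(2)

    def __post_init__(self) -> None:
        for name in ("duplication", "transfer", "loss", "origin", "rearrangement"):
            object.__setattr__(self, name, _as_cost(getattr(self, name)))

    # single-letter aliases matching the field's usual notation
    @property
    def D(self) -> Fraction:
        return self.duplication

    @property
    def T(self) -> Fraction:
        return self.transfer

    @property
    def L(self) -> Fraction:
        return self.loss

    @property
    def O(self) -> Fraction:  # noqa: E743 - standard symbol
        return self.origin

    @property
    def R(self) -> Fraction:
        return self.rearrangement


@dataclass(frozen=True)
class Instance:
    """A DTLOR reconciliation problem: two trees, tip data, event costs."""

    species_tree: RootedTree
    gene_tree: RootedTree
    assoc: LeafAssociation
    costs: EventCosts = field(default_factory=EventCosts)

    def __post_init__(self) -> None:
        if not self.species_tree.is_binary:
            raise InputError("species tree must be binary")
        self.assoc.validate(self.gene_tree, self.species_tree)


@dataclass(frozen=True)
class EventRecord:
    """One induced event.

    ``species`` is the species vertex at which the event happens: the image
    of the gene vertex for speciation/duplication/transfer/origin, or the
    passed-through vertex for a loss.  For a rearrangement, ``synteny``
    holds the ``(parent_label, child_label)`` pair on the gene edge.
    """

    kind: str
    gene: str
    species: str | None = None
    synteny: tuple[int, int] | None = None


@dataclass
class Reconciliation:
    """A (Phi, Gamma) pair for a gene tree against a species tree."""

    gene_tree: RootedTree
    species_tree: RootedTree
    species_map: dict[str, str | None]
    synteny_map: dict[str, int | None]

    def events(self) -> list[EventRecord]:
        return infer_events(
            self.gene_tree, self.species_tree, self.species_map, self.synteny_map
        )


def classify_vertex_event(
    species_tree: RootedTree,
    gene_tree: RootedTree,
    g: str,
    species_map: Mapping[str, str | None],
) -> str | None:
    """Classify the event induced at internal gene vertex ``g``.

    Returns one of speciation/duplication/transfer, or None when ``g`` maps
    to the outside location N (such vertices induce no DTL event).  Assumes
    the map satisfies the placement constraints; an inconsistent map raises.
    """
    s = species_map[g]
    if s is None:
        return None
    kids = gene_tree.children(g)
    if len(kids) != 2:
        raise InputError(f"gene vertex {g!r} is not binary")
    t1, t2 = (species_map[k] for k in kids)
    if t1 is None or t2 is None:
        raise InputError(f"children of mapped vertex {g!r} must be mapped")
    S = species_tree

    def under(child_image: str, side: str) -> bool:
        return child_image == side or S.is_ancestor(side, child_image)

    below1 = t1 == s or S.is_ancestor(s, t1)
    below2 = t2 == s or S.is_ancestor(s, t2)
    if below1 and below2:
        if not S.is_leaf(s):
            s1, s2 = S.children(s)
            if (under(t1, s1) and under(t2, s2)) or (under(t1, s2) and under(t2, s1)):
                return SPECIATION
        return DUPLICATION
    if below1 != below2:
        other = t2 if below1 else t1
        if not S.are_comparable(other, s):
            return TRANSFER
    raise InputError(f"species map violates placement constraints at {g!r}")


def infer_losses(
    species_tree: RootedTree,
    gene_tree: RootedTree,
    g: str,
    species_map: Mapping[str, str | None],
) -> list[str]:
    """Species vertices through which non-root gene vertex ``g`` passes.

    A loss is induced at every vertex on the path from ``Phi(p(g))`` down to
    ``Phi(g)``, excluding ``Phi(g)`` itself, and excluding ``Phi(p(g))``
    exactly when ``p(g)`` induces a speciation (after a duplication or a
    transfer, the child lineage still has to survive the subsequent
    speciation at that vertex, so the top endpoint does count).  Entry from
    outside (``Phi(p(g)) is None``) induces no losses: there is no path.
    """
    p = gene_tree.parent(g)
    if p is None:
        return []
    sp, sg = species_map[p], species_map[g]
    if sp is None or sg is None or sp == sg:
        return []
    if not species_tree.is_ancestor(sp, sg):
        return []
    path = species_tree.path_down(sp, sg)[:-1]  # drop Phi(g)
    if classify_vertex_event(species_tree, gene_tree, p, species_map) == SPECIATION:
        path = path[1:]
    return path


def infer_or_events(
    gene_tree: RootedTree, synteny_map: Mapping[str, int | None]
) -> list[EventRecord]:
    """Origin and rearrangement events induced by a synteny labeling."""
    out: list[EventRecord] = []
    for g in gene_tree.postorder:
        lab = synteny_map[g]
        p = gene_tree.parent(g)
        if lab is None:
            continue
        if p is None or synteny_map[p] is None:
            out.append(EventRecord(ORIGIN, g))
        elif synteny_map[p] != lab:
            out.append(
                EventRecord(REARRANGEMENT, g, synteny=(synteny_map[p], lab))
            )
    return out


def infer_events(
    gene_tree: RootedTree,
    species_tree: RootedTree,
    species_map: Mapping[str, str | None],
    synteny_map: Mapping[str, int | None],
) -> list[EventRecord]:
    """The full induced event list of a reconciliation (a pure function)."""
    out: list[EventRecord] = []
    for g in gene_tree.postorder:
        s = species_map[g]
        if s is not None and not gene_tree.is_leaf(g):
            kind = classify_vertex_event(species_tree, gene_tree, g, species_map)
            if kind != SPECIATION:
                out.append(EventRecord(kind, g, species=s))
        if s is not None:
            for passed in infer_losses(species_tree, gene_tree, g, species_map):
                out.append(EventRecord(LOSS, g, species=passed))
    for ev in infer_or_events(gene_tree, synteny_map):
        if ev.kind == ORIGIN:
            out.append(
                EventRecord(ORIGIN, ev.gene, species=species_map[ev.gene])
            )
        else:
            out.append(ev)
    return out


def event_counts(events: Iterable[EventRecord]) -> dict[str, int]:
    counts = {
        DUPLICATION: 0,
        TRANSFER: 0,
        LOSS: 0,
        ORIGIN: 0,
        REARRANGEMENT: 0,
    }
    for ev in events:
        if ev.kind in counts:
            counts[ev.kind] += 1
    return counts


def validate_reconciliation(rec: Reconciliation, instance: Instance) -> list[str]:
    """Check every placement and labeling constraint; return the violations.

    An empty list means the reconciliation is valid.  Each violation names
    the offending gene vertex and the rule it breaks.
    """
    G, S = rec.gene_tree, rec.species_tree
    Phi, Gamma = rec.species_map, rec.synteny_map
    phi, gamma = instance.assoc.phi, instance.assoc.gamma
    labels = instance.assoc.labels
    bad: list[str] = []

    for g in G.postorder:
        if g not in Phi:
            bad.append(f"{g}: missing from species map")
            continue
        if g not in Gamma:
            bad.append(f"{g}: missing from synteny map")
            continue
        s, lab = Phi[g], Gamma[g]
        if s is not None and s not in S:
            bad.append(f"{g}: species image {s!r} not in species tree")
            continue
        if lab is not None and lab not in labels:
            bad.append(f"{g}: synteny label {lab!r} not in L")
        if (s is None) != (lab is None):
            bad.append(f"{g}: Phi(g)=N iff Gamma(g)=* violated")
        if G.is_leaf(g):
            if s != phi.get(g):
                bad.append(f"{g}: leaf species map disagrees with phi")
            if lab != gamma.get(g):
                bad.append(f"{g}: leaf synteny disagrees with gamma")
            continue
        kids = G.children(g)
        if lab is not None and any(Gamma.get(k) is None for k in kids):
            bad.append(f"{g}: actual syntenic region but a child is labeled *")
        if s is None:
            continue
        images = [Phi.get(k) for k in kids]
        if any(t is None for t in images):
            bad.append(f"{g}: mapped vertex has a child mapped to N (2a)")
            continue
        if any(S.is_ancestor(t, s) for t in images):
            bad.append(f"{g}: child image is a proper ancestor of Phi(g) (2b)")
            continue
        below = [t == s or S.is_ancestor(s, t) for t in images]
        if not any(below):
            bad.append(f"{g}: no child image equal to or below Phi(g) (2c)")
    return bad


def _cost_json(value):
    f = Fraction(value)
    return int(f) if f.denominator == 1 else f"{f.numerator}/{f.denominator}"


def reconciliation_report(rec: Reconciliation, costs: EventCosts) -> dict:
    """JSON-ready report of a reconciliation (schema version 1).

    Per-gene-vertex records give the species image (``"N"`` for outside)
    and syntenic region (``"*"`` for unknown) plus the DTL event the vertex
    induces; a flat event list and the weighted total follow.
    """
    events = rec.events()
    by_vertex = {
        ev.gene: ev.kind for ev in events if ev.kind in (DUPLICATION, TRANSFER)
    }
    vertices = []
    for g in rec.gene_tree.postorder:
        s, lab = rec.species_map[g], rec.synteny_map[g]
        kind = by_vertex.get(g)
        if kind is None and s is not None and not rec.gene_tree.is_leaf(g):
            kind = SPECIATION
        vertices.append(
            {
                "vertex": g,
                "species": "N" if s is None else s,
                "synteny": "*" if lab is None else lab,
                "event": kind,
            }
        )
    ev_json = []
    for ev in events:
        item = {"kind": ev.kind, "gene": ev.gene}
        if ev.species is not None:
            item["species"] = ev.species
        if ev.synteny is not None:
            item["from_region"], item["to_region"] = ev.synteny
        ev_json.append(item)
    return {
        "schema_version": 1,
        "total_cost": _cost_json(score_reconciliation(rec, costs)),
        "event_counts": event_counts(events),
        "vertices": vertices,
        "events": ev_json,
    }


def score_reconciliation(rec: Reconciliation, costs: EventCosts) -> Fraction:
    """Total cost of a reconciliation: weighted event counts, speciation free."""
    counts = event_counts(rec.events())
    return (
        costs.duplication * counts[DUPLICATION]
        + costs.transfer * counts[TRANSFER]
        + costs.loss * counts[LOSS]
        + costs.origin * counts[ORIGIN]
        + costs.rearrangement * counts[REARRANGEMENT]
    )
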