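"""Brute-force reference solvers, used exclusively by the test suite.

These enumerate the full space of valid reconciliations (or of complete
binary resolutions) and score every candidate through the event-inference
path of :mod:`dtlor.model`.  They are written for obvious correctness, not
speed, and refuse instances above a hard size guard.

Because the species map and the synteny labeling interact only through the
shared outside set (the vertices at N, equivalently at ``*``), enumeration
groups valid maps by that set and combines per-set minima, which keeps the
search tractable without any cleverness in the scoring itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

from .exceptions import GuardError
from .model import (
    DUPLICATION,
    SPECIATION,
    TRANSFER,
    Instance,
    classify_vertex_event,
    infer_losses,
)
from .trees import RootedTree

__all__ = [
    "OracleResult",
    "enumerate_valid_species_maps",
    "brute_force_opt",
    "brute_force_nonbinary",
    "enumerate_full_resolutions",
]

MAX_GENE_VERTICES = 13
MAX_SPECIES_VERTICES = 9
MAX_TOTAL_RESOLUTIONS = 10_000


@dataclass
class OracleResult:
    cost: object
    count: int | None
    pairs: list[tuple[dict, dict]] | None = None


def enumerate_valid_species_maps(
    gene_tree: RootedTree, species_tree: RootedTree, phi
) -> list[dict[str, str | None]]:
    """All maps Phi from gene vertices to species vertices or N (= None).

    A map is valid when leaves follow ``phi`` and every internal vertex
    mapped inside the species tree has both children mapped inside, no
    child image ancestral to its own, and at least one child image at or
    below it.  Enumeration assigns vertices in postorder and prunes as it
    goes.
    """
    G, S = gene_tree, species_tree
    if len(G) > MAX_GENE_VERTICES or len(S) > MAX_SPECIES_VERTICES:
        raise GuardError(
            f"instance too large for brute force ({len(G)} gene, {len(S)} species vertices)"
        )
    maps: list[dict[str, str | None]] = [{}]
    for g in G.postorder:
        if G.is_leaf(g):
            for m in maps:
                m[g] = phi[g]
            continue
        kids = G.children(g)
        new_maps: list[dict[str, str | None]] = []
        for m in maps:
            images = [m[k] for k in kids]
            m_none = dict(m)
            m_none[g] = None
            new_maps.append(m_none)
            if any(t is None for t in images):
                continue
            for s in S.postorder:
                if any(S.is_ancestor(t, s) for t in images):
                    continue
                if not any(t == s or S.is_ancestor(s, t) for t in images):
                    continue
                m_s = dict(m)
                m_s[g] = s
                new_maps.append(m_s)
        maps = new_maps
    return maps


def _enumerate_valid_labelings(gene_tree: RootedTree, gamma, labels):
    """All Gamma maps: leaves follow gamma; an actual label forbids * children."""
    G = gene_tree
    labs = sorted(labels)
    maps: list[dict[str, int | None]] = [{}]
    for g in G.postorder:
        if G.is_leaf(g):
            for m in maps:
                m[g] = gamma[g]
            continue
        kids = G.children(g)
        new_maps = []
        for m in maps:
            child_has_star = any(m[k] is None for k in kids)
            m_star = dict(m)
            m_star[g] = None
            new_maps.append(m_star)
            if child_has_star:
                continue
            for lab in labs:
                m_l = dict(m)
                m_l[g] = lab
                new_maps.append(m_l)
        maps = new_maps
    return maps


def _dtl_cost(instance: Instance, species_map) -> Fraction:
    G, S = instance.gene_tree, instance.species_tree
    c = instance.costs
    total = Fraction(0)
    for g in G.postorder:
        s = species_map[g]
        if s is None:
            continue
        if not G.is_leaf(g):
            kind = classify_vertex_event(S, G, g, species_map)
            if kind == DUPLICATION:
                total += c.duplication
            elif kind == TRANSFER:
                total += c.transfer
            else:
                assert kind == SPECIATION
        total += c.loss * len(infer_losses(S, G, g, species_map))
    return total


def _or_cost(instance: Instance, synteny_map) -> Fraction:
    G = instance.gene_tree
    c = instance.costs
    total = Fraction(0)
    for g in G.postorder:
        lab = synteny_map[g]
        if lab is None:
            continue
        p = G.parent(g)
        if p is None or synteny_map[p] is None:
            total += c.origin
        elif synteny_map[p] != lab:
            total += c.rearrangement
    return total


def brute_force_opt(instance: Instance, include_pairs: bool = False) -> OracleResult:
    """Exhaustive optimum over all valid (Phi, Gamma) pairs.

    The two maps must share their outside set (Phi(g)=N iff Gamma(g)=*),
    and given that set their costs add independently, so the minimum and
    the exact count of co-optimal pairs factor per set.
    """
    G = instance.gene_tree
    by_nset: dict[frozenset, list] = {}
    for Phi in enumerate_valid_species_maps(
        G, instance.species_tree, instance.assoc.phi
    ):
        key = frozenset(g for g, s in Phi.items() if s is None)
        by_nset.setdefault(key, []).append((_dtl_cost(instance, Phi), Phi))
    by_starset: dict[frozenset, list] = {}
    for Gam in _enumerate_valid_labelings(G, instance.assoc.gamma, instance.assoc.labels):
        key = frozenset(g for g, l in Gam.items() if l is None)
        by_starset.setdefault(key, []).append((_or_cost(instance, Gam), Gam))

    best = None
    for key, phis in by_nset.items():
        gams = by_starset.get(key)
        if not gams:
            continue
        total = min(c for c, _ in phis) + min(c for c, _ in gams)
        if best is None or total < best:
            best = total
    if best is None:
        raise GuardError("no valid reconciliation exists (should be impossible)")

    count = 0
    pairs: list[tuple[dict, dict]] | None = [] if include_pairs else None
    for key, phis in by_nset.items():
        gams = by_starset.get(key)
        if not gams:
            continue
        pmin = min(c for c, _ in phis)
        gmin = min(c for c, _ in gams)
        if pmin + gmin != best:
            continue
        popt = [m for c, m in phis if c == pmin]
        gopt = [m for c, m in gams if c == gmin]
        count += len(popt) * len(gopt)
        if pairs is not None:
            pairs.extend((p, q) for p in popt for q in gopt)
    return OracleResult(cost=best, count=count, pairs=pairs)


# -- non-binary: exhaustive resolutions ------------------------------------


def _splice(children_map: dict, vertex: str, resolution, child_names, fresh):
    """Replace a multifurcation by one binary resolution (nested index pairs)."""

    def build(sub) -> str:
        if isinstance(sub, int):
            return child_names[sub]
        name = fresh()
        children_map[name] = (build(sub[0]), build(sub[1]))
        return name

    left, right = resolution
    children_map[vertex] = (build(left), build(right))


def enumerate_full_resolutions(gene_tree: RootedTree) -> list[RootedTree]:
    """Every complete binary resolution of a multifurcating gene tree."""
    from .nonbinary import enumerate_resolutions

    G = gene_tree
    poly = [g for g in G.postorder if len(G.children(g)) > 2]
    per_vertex = [enumerate_resolutions(range(len(G.children(g)))) for g in poly]
    total = 1
    for opts in per_vertex:
        total *= len(opts)
    if total > MAX_TOTAL_RESOLUTIONS:
        raise GuardError(f"{total} full resolutions exceed the oracle guard")

    counter = itertools.count()
    out: list[RootedTree] = []
    for combo in itertools.product(*per_vertex) if poly else [()]:
        children_map = {g: tuple(G.children(g)) for g in G.postorder}

        def fresh() -> str:
            while True:
                name = f"+x{next(counter)}"
                if name not in children_map:
                    return name

        for vertex, resolution in zip(poly, combo):
            _splice(children_map, vertex, resolution, list(G.children(vertex)), fresh)
        out.append(RootedTree(G.root, children_map))
    return out


def brute_force_nonbinary(instance: Instance, solver: str = "dp") -> OracleResult:
    """Optimum over all complete binary resolutions of the gene tree.

    Each resolution is scored by the binary pipeline (``solver="dp"``) or by
    :func:`brute_force_opt` (``solver="enumerate"``).  Counting of distinct
    reconciliations across resolutions is not defined, so ``count`` is None.
    """
    from .mpr import solve

    best = None
    for resolved in enumerate_full_resolutions(instance.gene_tree):
        sub = Instance(instance.species_tree, resolved, instance.assoc, instance.costs)
        if solver == "dp":
            cost, _ = solve(sub)
        else:
            cost = brute_force_opt(sub).cost
        if best is None or cost < best:
            best = cost
    return OracleResult(cost=best, count=None)
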