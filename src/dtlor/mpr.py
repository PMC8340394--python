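"""Optimal DTLOR reconciliation for binary gene trees.

The species DP and the synteny DP decouple inside each origin subtree, so
the full problem reduces to choosing where origin events happen:

* ``Origin(g) = O + C(g) + syn(g)`` — reconcile G(g) as one origin subtree;
* ``Null(g)`` — g itself stays outside the species tree (label ``*``),
  which is impossible for leaves and otherwise sums, over the children, the
  cheaper of staying outside or starting an origin subtree;
* ``Opt = min(Null(root), Origin(root))``.

Alongside the optimum this module provides a deterministic traceback to a
full reconciliation and an exact count of co-optimal ``(Phi, Gamma)`` pairs.
Counting works on the *terminates* table, which puts dynamic-programming
traces in bijection with species maps; duplication cells exclude child
placements that actually form a speciation pattern, and transfer landings
are counted over termination sites only.  Without this care, zero event
costs (which this package accepts) would make the count ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    EventCosts,
    Instance,
    Reconciliation,
    score_reconciliation,
    validate_reconciliation,
)
from .species_dp import INF, SpeciesTables, compute_species_tables
from .synteny_dp import SyntenyTables, compute_synteny_tables

__all__ = ["CombineTables", "MPRTables", "solve", "traceback", "count_mprs", "reconcile"]


@dataclass
class CombineTables:
    origin: dict[str, object]
    null: dict[str, object]
    opt: object


@dataclass
class MPRTables:
    species: SpeciesTables
    synteny: SyntenyTables
    combine: CombineTables


def solve(instance: Instance) -> tuple[object, MPRTables]:
    """Compute Opt and all DP tables for a binary instance."""
    G = instance.gene_tree
    O = instance.costs.origin
    st = compute_species_tables(instance)
    syt = compute_synteny_tables(
        G, instance.assoc.gamma, instance.assoc.labels, instance.costs.rearrangement
    )
    origin: dict[str, object] = {}
    null: dict[str, object] = {}
    for g in G.postorder:
        origin[g] = O + st.opt[g] + syt.opt[g]
        if G.is_leaf(g):
            null[g] = INF
        else:
            null[g] = sum(
                min(null[c], origin[c]) for c in G.children(g)
            )
    root = G.root
    opt = min(null[root], origin[root])
    return opt, MPRTables(st, syt, CombineTables(origin, null, opt))


# -- traceback -------------------------------------------------------------


def traceback(
    instance: Instance,
    species_tables: SpeciesTables,
    synteny_tables: SyntenyTables,
    combine_tables: CombineTables,
) -> Reconciliation:
    """Reconstruct one optimal reconciliation, deterministically.

    Tie-breaking: Null before Origin; at a C cell speciation, then loss,
    then duplication, then transfer; among species edges the first in
    postorder; among labels the smallest; a child keeps its parent's region
    when switching would cost the same.  The traced reconciliation is
    validated and re-scored through the event-inference path; any
    disagreement with Opt is an internal bug and raises ``AssertionError``.
    """
    G, S = instance.gene_tree, instance.species_tree
    costs = instance.costs
    D, T, L, R = costs.duplication, costs.transfer, costs.loss, costs.rearrangement
    st, syt, ct = species_tables, synteny_tables, combine_tables
    sp = S.postorder
    n = len(sp)
    sidx = {s: i for i, s in enumerate(sp)}
    s_kids = [tuple(sidx[c] for c in S.children(s)) for s in sp]

    Phi: dict[str, str | None] = {}
    Gamma: dict[str, int | None] = {}

    def incomparable(i: int, j: int) -> bool:
        return not S.are_comparable(sp[i], sp[j])

    def do_event(g: str, i: int, kind: str) -> None:
        Phi[g] = sp[i]
        g1, g2 = G.children(g)
        p1, p2 = st.placed[g1], st.placed[g2]
        if kind == "spec":
            a, b = s_kids[i]
            if p1[a] + p2[b] <= p1[b] + p2[a]:
                trace_placed(g1, a), trace_placed(g2, b)
            else:
                trace_placed(g1, b), trace_placed(g2, a)
        elif kind == "dup":
            trace_placed(g1, i)
            trace_placed(g2, i)
        else:  # transfer
            bt1, bt2 = st.best_transfer[g1], st.best_transfer[g2]
            if p1[i] + bt2[i] <= p2[i] + bt1[i]:
                stay, moved = g1, g2
            else:
                stay, moved = g2, g1
            trace_placed(stay, i)
            landing = st.best_transfer[moved][i]
            trow = st.term[moved]
            for j in range(n):
                if incomparable(j, i) and trow[j] == landing:
                    trace_term(moved, j)
                    break
            else:  # pragma: no cover - bug trap
                raise AssertionError("no transfer landing site found")

    def event_candidates(g: str, i: int) -> list[tuple[str, object]]:
        g1, g2 = G.children(g)
        p1, p2 = st.placed[g1], st.placed[g2]
        bt1, bt2 = st.best_transfer[g1], st.best_transfer[g2]
        cands: list[tuple[str, object]] = []
        if s_kids[i]:
            a, b = s_kids[i]
            cands.append(("spec", min(p1[a] + p2[b], p1[b] + p2[a])))
        cands.append(("dup", D + p1[i] + p2[i]))
        cands.append(("transfer", T + min(p1[i] + bt2[i], p2[i] + bt1[i])))
        return cands

    def trace_term(g: str, i: int) -> None:
        if G.is_leaf(g):
            Phi[g] = sp[i]
            return
        target = st.term[g][i]
        for kind, val in event_candidates(g, i):
            if val == target:
                do_event(g, i, kind)
                return
        raise AssertionError("terminate cell does not match any event")

    def trace_placed(g: str, i: int) -> None:
        target = st.placed[g][i]
        prow = st.placed[g]
        # ordered candidates: speciation, loss, duplication, transfer
        if G.is_leaf(g):
            if st.term[g][i] == target:
                Phi[g] = sp[i]
                return
        else:
            cands = event_candidates(g, i)
            if cands[0][0] == "spec" and cands[0][1] == target:
                do_event(g, i, "spec")
                return
        if s_kids[i]:
            a, b = s_kids[i]
            if L + prow[a] == target:
                trace_placed(g, a)
                return
            if L + prow[b] == target:
                trace_placed(g, b)
                return
        if not G.is_leaf(g):
            for kind, val in event_candidates(g, i):
                if kind != "spec" and val == target:
                    do_event(g, i, kind)
                    return
        raise AssertionError("placed cell does not match any alternative")

    def trace_synteny(g: str, lab: int) -> None:
        Gamma[g] = lab
        if G.is_leaf(g):
            return
        for c in G.children(g):
            if syt.syn[c][lab] <= R + syt.opt[c]:
                trace_synteny(c, lab)
            else:
                for l2 in syt.labels:
                    if syt.syn[c][l2] == syt.opt[c]:
                        trace_synteny(c, l2)
                        break

    def trace_origin(g: str) -> None:
        for lab in syt.labels:
            if syt.syn[g][lab] == syt.opt[g]:
                trace_synteny(g, lab)
                break
        trow = st.term[g]
        for i in range(n):
            if trow[i] == st.opt[g]:
                trace_term(g, i)
                return
        raise AssertionError("no terminating cell achieves C(g)")

    def trace_combine(g: str) -> None:
        if ct.null[g] <= ct.origin[g]:
            Phi[g] = None
            Gamma[g] = None
            for c in G.children(g):
                trace_combine(c)
        else:
            trace_origin(g)

    trace_combine(G.root)

    rec = Reconciliation(G, S, Phi, Gamma)
    problems = validate_reconciliation(rec, instance)
    if problems:  # pragma: no cover - bug trap
        raise AssertionError(f"traceback produced an invalid reconciliation: {problems}")
    if score_reconciliation(rec, costs) != ct.opt:  # pragma: no cover - bug trap
        raise AssertionError("traceback score disagrees with Opt")
    return rec


# -- exact counting --------------------------------------------------------


def count_mprs(instance: Instance, tables: MPRTables) -> int:
    """Exact number of distinct optimal (Phi, Gamma) pairs.

    Loss placements are a function of Phi (the unique tree path), so
    counting termination sites counts reconciliations.  Arbitrary-precision
    integers; requires the tables returned by :func:`solve`.
    """
    G, S = instance.gene_tree, instance.species_tree
    costs = instance.costs
    D, T, L, R = costs.duplication, costs.transfer, costs.loss, costs.rearrangement
    st, syt, ct = tables.species, tables.synteny, tables.combine
    sp = S.postorder
    n = len(sp)
    sidx = {s: i for i, s in enumerate(sp)}
    s_kids = [tuple(sidx[c] for c in S.children(s)) for s in sp]
    s_parent = [sidx[S.parent(s)] if S.parent(s) is not None else None for s in sp]

    termcnt: dict[str, list[int]] = {}
    placedcnt: dict[str, list[int]] = {}
    becnt: dict[str, list[int]] = {}
    btcnt: dict[str, list[int]] = {}

    for g in G.postorder:
        trow, prow = st.term[g], st.placed[g]
        tc = [0] * n
        pc = [0] * n
        if G.is_leaf(g):
            tc[sidx[instance.assoc.phi[g]]] = 1
        else:
            g1, g2 = G.children(g)
            p1, p2 = st.placed[g1], st.placed[g2]
            t1, t2 = st.term[g1], st.term[g2]
            pc1, pc2 = placedcnt[g1], placedcnt[g2]
            tc1, tc2 = termcnt[g1], termcnt[g2]
            bt1, bt2 = st.best_transfer[g1], st.best_transfer[g2]
            bc1, bc2 = btcnt[g1], btcnt[g2]
            for i in range(n):
                target = trow[i]
                if target == INF:
                    continue
                total = 0
                kids = s_kids[i]
                if kids:
                    a, b = kids
                    # speciation: children split across the two subtrees
                    if p1[a] + p2[b] == target:
                        total += pc1[a] * pc2[b]
                    if p1[b] + p2[a] == target:
                        total += pc1[b] * pc2[a]
                    # duplication: both children at or below s, but not a
                    # speciation pattern.  Decompose each child's placement
                    # as: terminate at s / enter subtree a / enter subtree b.
                    groups1 = ((t1[i], tc1[i]), (L + p1[a], pc1[a]), (L + p1[b], pc1[b]))
                    groups2 = ((t2[i], tc2[i]), (L + p2[a], pc2[a]), (L + p2[b], pc2[b]))
                    for x in range(3):
                        for y in range(3):
                            if (x, y) in ((1, 2), (2, 1)):
                                continue  # that's the speciation pattern
                            v1, c1 = groups1[x]
                            v2, c2 = groups2[y]
                            if c1 and c2 and D + v1 + v2 == target:
                                total += c1 * c2
                else:
                    if D + t1[i] + t2[i] == target:
                        total += tc1[i] * tc2[i]
                # transfer: either child lands on an incomparable edge
                if T + p1[i] + bt2[i] == target:
                    total += pc1[i] * bc2[i]
                if T + p2[i] + bt1[i] == target:
                    total += pc2[i] * bc1[i]
                tc[i] = total
        for i in range(n):
            if prow[i] == INF:
                continue
            c = tc[i] if trow[i] == prow[i] else 0
            for a in s_kids[i]:
                if L + st.placed[g][a] == prow[i]:
                    c += pc[a]
            pc[i] = c
        termcnt[g] = tc
        placedcnt[g] = pc

        be = st.best_entry[g]
        bc = [0] * n
        for i in range(n):
            c = tc[i] if trow[i] == be[i] else 0
            for a in s_kids[i]:
                if be[a] == be[i]:
                    c += bc[a]
            bc[i] = c
        becnt[g] = bc
        bt = st.best_transfer[g]
        btc = [0] * n
        for i in range(n - 1, -1, -1):
            p = s_parent[i]
            if p is None:
                continue
            c = btc[p] if bt[p] == bt[i] else 0
            sib = s_kids[p][0] if s_kids[p][1] == i else s_kids[p][1]
            if be[sib] == bt[i]:
                c += bc[sib]
            btc[i] = c
        btcnt[g] = btc

    # synteny labeling counts
    syncnt: dict[str, dict[int, int]] = {}
    for g in G.postorder:
        if G.is_leaf(g):
            syncnt[g] = {
                lab: (1 if instance.assoc.gamma[g] == lab else 0)
                for lab in syt.labels
            }
            continue
        row: dict[int, int] = {}
        for lab in syt.labels:
            if syt.syn[g][lab] == INF:
                row[lab] = 0
                continue
            prod = 1
            for c in G.children(g):
                v = min(syt.syn[c][lab], R + syt.opt[c])
                cnt = syncnt[c][lab] if syt.syn[c][lab] == v else 0
                for l2 in syt.labels:
                    if l2 != lab and R + syt.syn[c][l2] == v:
                        cnt += syncnt[c][l2]
                prod *= cnt
            row[lab] = prod
        syncnt[g] = row

    def phi_count(g: str) -> int:
        return sum(
            termcnt[g][i] for i in range(n) if st.term[g][i] == st.opt[g]
        )

    def gamma_count(g: str) -> int:
        return sum(
            syncnt[g][lab] for lab in syt.labels if syt.syn[g][lab] == syt.opt[g]
        )

    origincnt: dict[str, int] = {}
    nullcnt: dict[str, int] = {}
    for g in G.postorder:
        origincnt[g] = phi_count(g) * gamma_count(g)
        if G.is_leaf(g):
            nullcnt[g] = 0
        else:
            prod = 1
            for c in G.children(g):
                m = min(ct.null[c], ct.origin[c])
                cnt = nullcnt[c] if ct.null[c] == m else 0
                if ct.origin[c] == m:
                    cnt += origincnt[c]
                prod *= cnt
            nullcnt[g] = prod

    root = G.root
    total = 0
    if ct.null[root] == ct.opt:
        total += nullcnt[root]
    if ct.origin[root] == ct.opt:
        total += origincnt[root]
    return total


# -- convenience -----------------------------------------------------------


@dataclass
class ReconcileResult:
    opt: object
    reconciliation: Reconciliation
    tables: MPRTables
    mpr_count: int | None = None


def reconcile(instance: Instance, count: bool = False) -> ReconcileResult:
    """Solve, trace back, and optionally count, in one call."""
    opt, tables = solve(instance)
    rec = traceback(instance, tables.species, tables.synteny, tables.combine)
    cnt = count_mprs(instance, tables) if count else None
    return ReconcileResult(opt=opt, reconciliation=rec, tables=tables, mpr_count=cnt)
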