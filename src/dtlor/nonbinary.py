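"""Joint species/synteny DP for multifurcating gene trees.

For binary gene trees the species map and the synteny labeling decouple
inside each origin subtree.  With soft polytomies they do not: the binary
resolution of a multifurcation that is best for the species map can differ
from the one best for the labeling, so the DP here carries both at once.
The cell ``C(e_g, e_s, l)`` is the optimal cost of reconciling G(g) with
``e_g`` placed on ``e_s`` and g in syntenic region ``l``; every child term
in the speciation/duplication/transfer alternatives chooses between
keeping the parent's region and paying R for the cheapest other one, and
Best-Transfer is likewise indexed by region.

Each multifurcation with children ``g_1..g_k`` is expanded into all
(2k-3)!! binary resolutions; a resolution's leaf edges inherit the already
merged tables of the children, so resolutions compose additively rather
than multiplicatively across vertices.  A vertex evolving outside the
species tree (region ``*``) contributes no events, but an origin may occur
at a vertex *internal to a resolution*, grouping several children under a
single origin subtree — the Null recursion therefore also runs inside each
resolution.  Runtime is O(f(k) k |G| |S| |L|) with f(k) the resolution
count for the largest multifurcation.

As in the binary solver, a parallel *terminates* table (cost with
``Phi(g) = s`` exactly) is kept alongside the placed table; the two have
identical subtree minima but the former makes traceback unambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .exceptions import ArityCapError, InputError
from .model import (
    Instance,
    Reconciliation,
    score_reconciliation,
    validate_reconciliation,
)
from .species_dp import INF
from .trees import RootedTree

__all__ = [
    "enumerate_resolutions",
    "resolution_count",
    "solve_nonbinary",
    "NonbinaryResult",
    "DEFAULT_MAX_ARITY",
]

DEFAULT_MAX_ARITY = 8


def resolution_count(k: int) -> int:
    """(2k-3)!!, the number of rooted binary trees on k labeled leaves."""
    out = 1
    for i in range(3, 2 * k - 2, 2):
        out *= i
    return out


def enumerate_resolutions(items, max_arity: int = DEFAULT_MAX_ARITY) -> list:
    """All rooted binary topologies over the given ordered items.

    Trees are nested 2-tuples whose leaves are the items.  Built by
    inserting each successive item on every edge (including above the
    root) of every smaller tree, which enumerates each topology exactly
    once: the count is (2k-3)!!.
    """
    items = list(items)
    k = len(items)
    if k < 2:
        raise InputError("a resolution needs at least two children")
    if k > max_arity:
        raise ArityCapError(
            f"multifurcation of arity {k} exceeds the cap {max_arity}; "
            "raise max_arity explicitly to resolve it"
        )

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            a, b = tree
            for t in insert_everywhere(a, leaf):
                yield (t, b)
            for t in insert_everywhere(b, leaf):
                yield (a, t)

    trees = [(items[0], items[1])]
    for leaf in items[2:]:
        trees = [t for tree in trees for t in insert_everywhere(tree, leaf)]
    return trees


# -- table plumbing --------------------------------------------------------


class _Scratch:
    """A vertex internal to one binary resolution of a multifurcation."""

    __slots__ = ("left", "right", "bundle", "name")

    def __init__(self, left, right):
        self.left = left
        self.right = right
        self.bundle = None
        self.name: str | None = None


@dataclass
class NonbinaryResult:
    opt: object
    resolved_tree: RootedTree
    reconciliation: Reconciliation
    origin: dict[str, object]
    null: dict[str, object]


def solve_nonbinary(
    instance: Instance, max_arity: int = DEFAULT_MAX_ARITY
) -> NonbinaryResult:
    """Optimal DTLOR reconciliation over all resolutions of the gene tree.

    Returns the optimum, one optimal fully resolved binary gene tree, and
    a reconciliation on it that validates and re-scores to the optimum.
    Already-binary inputs take the k=2 path and match the binary solver.
    """
    G, S = instance.gene_tree, instance.species_tree
    costs = instance.costs
    D, T, L = costs.duplication, costs.transfer, costs.loss
    O, R = costs.origin, costs.rearrangement
    phi, gamma = instance.assoc.phi, instance.assoc.gamma
    labs = tuple(sorted(instance.assoc.labels))
    m = len(labs)
    lpos = {lab: i for i, lab in enumerate(labs)}

    sp = S.postorder
    n = len(sp)
    sidx = {s: i for i, s in enumerate(sp)}
    s_kids = [tuple(sidx[c] for c in S.children(s)) for s in sp]
    s_parent = [sidx[S.parent(s)] if S.parent(s) is not None else None for s in sp]

    for g in G.postorder:
        if not G.is_leaf(g) and len(G.children(g)) < 2:
            raise InputError(f"gene vertex {g!r} has a single child")

    def aux(term):
        """Placed/Best-Entry/Best-Transfer rows derived from a term table."""
        placed = [[INF] * m for _ in range(n)]
        for i in range(n):
            kids = s_kids[i]
            for li in range(m):
                v = term[i][li]
                if kids:
                    a, b = kids
                    v = min(v, L + placed[a][li], L + placed[b][li])
                placed[i][li] = v
        placed_L = [min(row) for row in placed]
        be = [[INF] * m for _ in range(n)]
        for i in range(n):
            for li in range(m):
                v = placed[i][li]
                for c in s_kids[i]:
                    if be[c][li] < v:
                        v = be[c][li]
                be[i][li] = v
        bt = [[INF] * m for _ in range(n)]
        for i in range(n - 1, -1, -1):
            p = s_parent[i]
            if p is None:
                continue
            sib = s_kids[p][0] if s_kids[p][1] == i else s_kids[p][1]
            for li in range(m):
                bt[i][li] = min(bt[p][li], be[sib][li])
        bt_L = [min(row) for row in bt]
        min_term = min(min(row) for row in term)
        return {
            "term": term,
            "placed": placed,
            "placed_L": placed_L,
            "be": be,
            "bt": bt,
            "bt_L": bt_L,
            "min_term": min_term,
        }

    def child_opt(b, i, li):
        """Child placed on e_s_i: keep region li or rearrange to the best."""
        return min(b["placed"][i][li], R + b["placed_L"][i])

    def child_bt_opt(b, i, li):
        return min(b["bt"][i][li], R + b["bt_L"][i])

    def internal_term(b1, b2):
        term = [[INF] * m for _ in range(n)]
        for i in range(n):
            kids = s_kids[i]
            for li in range(m):
                c1 = child_opt(b1, i, li)
                c2 = child_opt(b2, i, li)
                dup = D + c1 + c2
                trans = T + min(
                    c1 + child_bt_opt(b2, i, li), c2 + child_bt_opt(b1, i, li)
                )
                best = dup if dup <= trans else trans
                if kids:
                    a, b = kids
                    spec = min(
                        child_opt(b1, a, li) + child_opt(b2, b, li),
                        child_opt(b1, b, li) + child_opt(b2, a, li),
                    )
                    if spec < best:
                        best = spec
                term[i][li] = best
        return term

    def bundle_of(ref):
        return tables[ref] if isinstance(ref, str) else ref.bundle

    tables: dict[str, dict] = {}
    origin: dict[str, object] = {}
    null: dict[str, object] = {}
    res_records: dict[str, list] = {}
    term_argH: dict[str, list] = {}
    null_argH: dict[str, int] = {}

    def contrib(ref):
        """min(Null, Origin) for a resolution node (original child or scratch)."""
        if isinstance(ref, str):
            return min(null[ref], origin[ref])
        b = ref.bundle
        return min(
            contrib(ref.left) + contrib(ref.right), O + b["min_term"]
        )

    for g in G.postorder:
        if G.is_leaf(g):
            term = [[INF] * m for _ in range(n)]
            term[sidx[phi[g]]][lpos[gamma[g]]] = 0
            tables[g] = aux(term)
            origin[g] = O + tables[g]["min_term"]
            null[g] = INF
            continue
        cs = list(G.children(g))
        records = []
        merged = [[INF] * m for _ in range(n)]
        argH = [[-1] * m for _ in range(n)]
        best_null = INF
        best_null_H = 0
        for hidx, H in enumerate(enumerate_resolutions(range(len(cs)), max_arity)):

            def build(sub):
                if isinstance(sub, int):
                    return cs[sub]
                node = _Scratch(build(sub[0]), build(sub[1]))
                node.bundle = aux(
                    internal_term(bundle_of(node.left), bundle_of(node.right))
                )
                return node

            left, right = build(H[0]), build(H[1])
            root_term = internal_term(bundle_of(left), bundle_of(right))
            for i in range(n):
                for li in range(m):
                    if root_term[i][li] < merged[i][li]:
                        merged[i][li] = root_term[i][li]
                        argH[i][li] = hidx
            null_H = contrib(left) + contrib(right)
            if null_H < best_null:
                best_null = null_H
                best_null_H = hidx
            records.append((left, right))
        tables[g] = aux(merged)
        origin[g] = O + tables[g]["min_term"]
        null[g] = best_null
        null_argH[g] = best_null_H
        res_records[g] = records
        term_argH[g] = argH

    root = G.root
    opt = min(null[root], origin[root])

    # ---- traceback -------------------------------------------------------

    Phi: dict[str, str | None] = {}
    Gamma: dict[str, int | None] = {}
    resolved_children: dict[str, tuple[str, str]] = {}
    scratch_counter = itertools.count()
    taken_names = set(G.postorder)

    def name_of(ref) -> str:
        if isinstance(ref, str):
            return ref
        if ref.name is None:
            while True:
                nm = f"+r{next(scratch_counter)}"
                if nm not in taken_names:
                    break
            ref.name = nm
            taken_names.add(nm)
        return ref.name

    def children_refs_at(ref, i, li):
        """The two resolution children used by the term cell (i, li)."""
        if isinstance(ref, str):
            left, right = res_records[ref][term_argH[ref][i][li]]
        else:
            left, right = ref.left, ref.right
        resolved_children[name_of(ref)] = (name_of(left), name_of(right))
        return left, right

    def pick_child_label(b, i, li) -> int:
        """Region index for a child placed on e_s_i under a parent in li."""
        if b["placed"][i][li] <= R + b["placed_L"][i]:
            return li
        for lj in range(m):
            if b["placed"][i][lj] == b["placed_L"][i]:
                return lj
        raise AssertionError("no region achieves the free minimum")

    def trace_term(ref, i, li) -> None:
        nm = name_of(ref)
        Phi[nm] = sp[i]
        Gamma[nm] = labs[li]
        if isinstance(ref, str) and G.is_leaf(ref):
            return
        target = bundle_of(ref)["term"][i][li]
        left, right = children_refs_at(ref, i, li)
        b1, b2 = bundle_of(left), bundle_of(right)
        kids = s_kids[i]
        if kids:
            a, b = kids
            for (ca, cb) in ((a, b), (b, a)):
                if child_opt(b1, ca, li) + child_opt(b2, cb, li) == target:
                    trace_placed(left, ca, pick_child_label(b1, ca, li))
                    trace_placed(right, cb, pick_child_label(b2, cb, li))
                    return
        c1 = child_opt(b1, i, li)
        c2 = child_opt(b2, i, li)
        if D + c1 + c2 == target:
            trace_placed(left, i, pick_child_label(b1, i, li))
            trace_placed(right, i, pick_child_label(b2, i, li))
            return
        for stay, moved, cstay, bmoved in (
            (left, right, c1, b2),
            (right, left, c2, b1),
        ):
            if T + cstay + child_bt_opt(bmoved, i, li) == target:
                bstay = bundle_of(stay)
                trace_placed(stay, i, pick_child_label(bstay, i, li))
                if bmoved["bt"][i][li] <= R + bmoved["bt_L"][i]:
                    lj = li
                else:
                    lj = next(
                        l2 for l2 in range(m)
                        if bmoved["bt"][i][l2] == bmoved["bt_L"][i]
                    )
                landing = bmoved["bt"][i][lj]
                for j in range(n):
                    if (
                        not S.are_comparable(sp[j], sp[i])
                        and bmoved["term"][j][lj] == landing
                    ):
                        trace_term(moved, j, lj)
                        return
                raise AssertionError("no transfer landing site found")
        raise AssertionError("term cell does not match any event")

    def trace_placed(ref, i, li) -> None:
        b = bundle_of(ref)
        target = b["placed"][i][li]
        kids = s_kids[i]
        if b["term"][i][li] == target:
            is_orig_leaf = isinstance(ref, str) and G.is_leaf(ref)
            if is_orig_leaf:
                nm = name_of(ref)
                Phi[nm] = sp[i]
                Gamma[nm] = labs[li]
                return
            # speciation first, then loss, then duplication/transfer
            left, right = children_refs_at(ref, i, li)
            b1, b2 = bundle_of(left), bundle_of(right)
            if kids:
                a, bb = kids
                spec = min(
                    child_opt(b1, a, li) + child_opt(b2, bb, li),
                    child_opt(b1, bb, li) + child_opt(b2, a, li),
                )
                if spec == target:
                    trace_term(ref, i, li)
                    return
        if kids:
            for a in kids:
                if L + b["placed"][a][li] == target:
                    trace_placed(ref, a, li)
                    return
        if b["term"][i][li] == target:
            trace_term(ref, i, li)
            return
        raise AssertionError("placed cell does not match any alternative")

    def trace_origin(ref) -> None:
        b = bundle_of(ref)
        for i in range(n):
            for li in range(m):
                if b["term"][i][li] == b["min_term"]:
                    trace_term(ref, i, li)
                    return
        raise AssertionError("no cell achieves the origin minimum")

    def trace_outside(ref) -> None:
        """ref stays at N/*: trace the cheaper of Null and Origin below it."""
        if isinstance(ref, str):
            if null[ref] <= origin[ref]:
                nm = ref
                Phi[nm] = None
                Gamma[nm] = None
                left, right = res_records[ref][null_argH[ref]]
                resolved_children[nm] = (name_of(left), name_of(right))
                trace_outside_child(left)
                trace_outside_child(right)
            else:
                trace_origin(ref)
        else:
            nl = contrib(ref.left) + contrib(ref.right)
            if nl <= O + ref.bundle["min_term"]:
                nm = name_of(ref)
                Phi[nm] = None
                Gamma[nm] = None
                resolved_children[nm] = (name_of(ref.left), name_of(ref.right))
                trace_outside_child(ref.left)
                trace_outside_child(ref.right)
            else:
                trace_origin(ref)

    def trace_outside_child(ref) -> None:
        trace_outside(ref)

    trace_outside(root)

    resolved = RootedTree(root, resolved_children)
    rec = Reconciliation(resolved, S, Phi, Gamma)
    resolved_instance = Instance(S, resolved, instance.assoc, costs)
    problems = validate_reconciliation(rec, resolved_instance)
    if problems:  # pragma: no cover - bug trap
        raise AssertionError(f"nonbinary traceback invalid: {problems}")
    if score_reconciliation(rec, costs) != opt:  # pragma: no cover - bug trap
        raise AssertionError("nonbinary traceback score disagrees with Opt")
    return NonbinaryResult(
        opt=opt,
        resolved_tree=resolved,
        reconciliation=rec,
        origin=origin,
        null=null,
    )
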