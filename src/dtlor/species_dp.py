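"""Species-mapping dynamic program for binary gene trees.

For each gene edge ``e_g`` and species edge ``e_s`` (edges are identified
with their terminus vertices, the root's edge being the handle) the DP
computes

* ``term(e_g, e_s)`` — the optimal cost of mapping the subtree G(g) with
  ``Phi(g) = s`` (the gene edge *terminates* on ``e_s``), and
* ``C(e_g, e_s)`` — the optimal cost with ``e_g`` *placed* on ``e_s``,
  i.e. terminating at ``s`` or continuing past it into one of its child
  edges, paying a loss per vertex passed.

``C`` satisfies the classical case split: at two leaves it is 0 when the
tip mapping agrees and infinity otherwise; otherwise it is the minimum of
the speciation, loss, duplication and transfer alternatives, where the
transfer child lands on the cheapest species edge incomparable to ``e_s``
(the Best-Transfer table, derived from Best-Entry, the cheapest placement
within each species subtree).  ``term`` is the same minimum without the
loss alternative; the two tables agree after minimising over a subtree, but
``term`` puts DP traces in bijection with species maps, which is what exact
solution counting and traceback need even when some costs are zero.

Per-cell work is constant, so filling the tables costs O(|G| |S|) time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import NotBinaryError
from .model import Instance
from .trees import RootedTree

__all__ = ["INF", "SpeciesTables", "compute_species_tables", "species_opt"]

INF = float("inf")


@dataclass
class SpeciesTables:
    """Filled DP tables for one instance.

    Rows are lists indexed by species postorder index; one row per gene
    vertex.  ``opt[g]`` is C(g), the cost of the best species mapping of
    G(g) over all placements (always finite: mapping everything to a single
    species leaf is available).
    """

    species_tree: RootedTree
    gene_tree: RootedTree
    term: dict[str, list]
    placed: dict[str, list]
    best_entry: dict[str, list]
    best_transfer: dict[str, list]
    opt: dict[str, object]

    def C(self, g: str, s: str):
        return self.placed[g][self.species_tree.postorder_index(s)]

    def terminate_cost(self, g: str, s: str):
        return self.term[g][self.species_tree.postorder_index(s)]

    def BestEntry(self, g: str, s: str):
        return self.best_entry[g][self.species_tree.postorder_index(s)]

    def BestTransfer(self, g: str, s: str):
        return self.best_transfer[g][self.species_tree.postorder_index(s)]


def compute_species_tables(instance: Instance) -> SpeciesTables:
    """Fill C, Best-Entry and Best-Transfer for every gene x species edge."""
    G, S = instance.gene_tree, instance.species_tree
    if not G.is_binary:
        raise NotBinaryError(
            "gene tree has a multifurcation; use dtlor.nonbinary.solve_nonbinary"
        )
    costs = instance.costs
    phi = instance.assoc.phi
    D, T, L = costs.duplication, costs.transfer, costs.loss

    sp = S.postorder
    n = len(sp)
    sidx = {s: i for i, s in enumerate(sp)}
    s_kids = [tuple(sidx[c] for c in S.children(s)) for s in sp]
    s_parent = [sidx[S.parent(s)] if S.parent(s) is not None else None for s in sp]

    term: dict[str, list] = {}
    placed: dict[str, list] = {}
    best_entry: dict[str, list] = {}
    best_transfer: dict[str, list] = {}
    opt: dict[str, object] = {}

    for g in G.postorder:
        trow = [INF] * n
        prow = [INF] * n
        if G.is_leaf(g):
            target = sidx[phi[g]]
            trow[target] = 0
            for i in range(n):
                kids = s_kids[i]
                if not kids:
                    prow[i] = trow[i]
                else:
                    prow[i] = min(trow[i], L + min(prow[kids[0]], prow[kids[1]]))
        else:
            g1, g2 = G.children(g)
            p1, p2 = placed[g1], placed[g2]
            bt1, bt2 = best_transfer[g1], best_transfer[g2]
            for i in range(n):
                kids = s_kids[i]
                dup = D + p1[i] + p2[i]
                trans = T + min(p1[i] + bt2[i], p2[i] + bt1[i])
                if kids:
                    a, b = kids
                    spec = min(p1[a] + p2[b], p1[b] + p2[a])
                    trow[i] = min(spec, dup, trans)
                    prow[i] = min(trow[i], L + min(prow[a], prow[b]))
                else:
                    trow[i] = min(dup, trans)
                    prow[i] = trow[i]
        term[g] = trow
        placed[g] = prow
        opt[g] = min(trow)

        be = [INF] * n
        for i in range(n):
            be[i] = prow[i]
            for c in s_kids[i]:
                if be[c] < be[i]:
                    be[i] = be[c]
        bt = [INF] * n
        for i in range(n - 1, -1, -1):  # preorder: root (handle) first
            if s_parent[i] is None:
                bt[i] = INF  # nothing is incomparable to the handle
            else:
                p = s_parent[i]
                sib = s_kids[p][0] if s_kids[p][1] == i else s_kids[p][1]
                bt[i] = min(bt[p], be[sib])
        best_entry[g] = be
        best_transfer[g] = bt

    return SpeciesTables(
        species_tree=S,
        gene_tree=G,
        term=term,
        placed=placed,
        best_entry=best_entry,
        best_transfer=best_transfer,
        opt=opt,
    )


def species_opt(tables: SpeciesTables, g: str):
    """C(g): the optimal species-mapping cost for the subtree G(g)."""
    return tables.opt[g]
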