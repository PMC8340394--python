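"""Synteny-labeling dynamic program.

Within an origin subtree every gene vertex carries an actual syntenic
region, and the only events at stake are rearrangements: a child in a
different region than its parent costs R.  ``syn(g, l)`` is the optimal
rearrangement cost of labeling the subtree G(g) with its root labeled
``l``; ``syn(g)`` minimises over the root label.  Leaves are pinned to
their observed region.  The unknown region ``*`` never enters these
tables — it is handled by the origin/null recursion in :mod:`dtlor.mpr`.

The table is dense over V(G) x L and fills in O(|G| |L|) time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .exceptions import InputError
from .species_dp import INF
from .trees import RootedTree

__all__ = ["SyntenyTables", "compute_synteny_tables", "synteny_opt"]


@dataclass
class SyntenyTables:
    gene_tree: RootedTree
    labels: tuple[int, ...]  # sorted actual regions
    syn: dict[str, dict[int, object]]  # syn[g][l]
    opt: dict[str, object]  # syn(g) = min over l

    def __getitem__(self, key):
        g, l = key
        return self.syn[g][l]


def compute_synteny_tables(
    gene_tree: RootedTree,
    gamma: Mapping[str, int],
    labels,
    rearrangement_cost,
) -> SyntenyTables:
    """Fill syn(g, l) for every gene vertex and actual syntenic region."""
    labs = tuple(sorted(labels))
    if not labs:
        raise InputError("the syntenic region set L is empty")
    R = rearrangement_cost
    syn: dict[str, dict[int, object]] = {}
    opt: dict[str, object] = {}
    for g in gene_tree.postorder:
        if gene_tree.is_leaf(g):
            lab = gamma[g]
            if lab not in labs:
                raise InputError(f"leaf {g!r} has region {lab!r} outside L")
            row = {l: (0 if l == lab else INF) for l in labs}
        else:
            kid_rows = [(syn[c], opt[c]) for c in gene_tree.children(g)]
            row = {}
            for l in labs:
                total = 0
                for crow, copt in kid_rows:
                    total += min(crow[l], R + copt)
                row[l] = total
        syn[g] = row
        opt[g] = min(row.values())
    return SyntenyTables(gene_tree=gene_tree, labels=labs, syn=syn, opt=opt)


def synteny_opt(tables: SyntenyTables, g: str):
    return tables.opt[g]
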