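"""Rooted trees, newick I/O and leaf-association tables.

Every vertex of a rooted tree is identified with its incoming edge: the edge
``e_v`` entering ``v`` from its parent.  The root's incoming edge is the
*handle*, an implicit edge from a virtual pre-root vertex, so a tree with
``n`` vertices has exactly ``n`` edges and iterating over edges is the same
as iterating over vertices.  The reconciliation dynamic programs in this
package are written entirely in terms of this identification.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .exceptions import InputError, ParseError

__all__ = [
    "RootedTree",
    "LeafAssociation",
    "parse_newick",
    "write_newick",
    "postorder_edges",
    "is_ancestor",
    "are_comparable",
    "read_associations",
]


class RootedTree:
    """A rooted tree with named vertices and ordered children.

    Parameters
    ----------
    root:
        Name of the root vertex.
    children:
        Mapping from each internal vertex name to the ordered tuple of its
        child names.  Leaves either map to an empty tuple or are simply
        absent from the mapping.
    generated:
        Names that were auto-assigned (unnamed internal vertices from a
        newick file); these are omitted when writing newick.
    """

    __slots__ = (
        "root",
        "_children",
        "_parent",
        "_postorder",
        "_index",
        "_leaves",
        "_depth",
        "_ancestors",
        "_generated",
    )

    def __init__(
        self,
        root: str,
        children: Mapping[str, Sequence[str]],
        generated: Iterable[str] = (),
    ) -> None:
        self.root = root
        self._children: dict[str, tuple[str, ...]] = {}
        self._parent: dict[str, str] = {}
        self._generated = frozenset(generated)

        seen: set[str] = set()
        stack = [root]
        order: list[str] = []
        while stack:
            v = stack.pop()
            if v in seen:
                raise InputError(f"vertex {v!r} reachable twice (cycle or reuse)")
            seen.add(v)
            order.append(v)
            kids = tuple(children.get(v, ()))
            self._children[v] = kids
            for c in kids:
                if c in self._parent:
                    raise InputError(f"vertex {c!r} has two parents")
                self._parent[c] = v
            stack.extend(reversed(kids))
        extra = set(children) - seen
        if extra:
            raise InputError(f"vertices unreachable from root: {sorted(extra)}")

        # postorder: children (in input order) before their parent
        post: list[str] = []
        walk: list[tuple[str, bool]] = [(root, False)]
        while walk:
            v, expanded = walk.pop()
            if expanded:
                post.append(v)
            else:
                walk.append((v, True))
                for c in reversed(self._children[v]):
                    walk.append((c, False))
        self._postorder: tuple[str, ...] = tuple(post)
        self._index = {v: i for i, v in enumerate(post)}
        self._leaves = tuple(v for v in post if not self._children[v])

        self._depth: dict[str, int] = {root: 0}
        self._ancestors: dict[str, frozenset[str]] = {root: frozenset()}
        for v in reversed(post):  # preorder-ish: parents before children
            for c in self._children[v]:
                self._depth[c] = self._depth[v] + 1
                self._ancestors[c] = self._ancestors[v] | {v}

    # -- basic structure ---------------------------------------------------

    def children(self, v: str) -> tuple[str, ...]:
        return self._children[v]

    def parent(self, v: str) -> str | None:
        """Parent of ``v``, or None for the root (its edge is the handle)."""
        return self._parent.get(v)

    def is_leaf(self, v: str) -> bool:
        return not self._children[v]

    @property
    def leaves(self) -> tuple[str, ...]:
        return self._leaves

    @property
    def postorder(self) -> tuple[str, ...]:
        return self._postorder

    def postorder_index(self, v: str) -> int:
        return self._index[v]

    def __contains__(self, v: str) -> bool:
        return v in self._children

    def __len__(self) -> int:
        return len(self._postorder)

    @property
    def vertices(self) -> tuple[str, ...]:
        return self._postorder

    @property
    def max_arity(self) -> int:
        return max((len(k) for k in self._children.values()), default=0)

    @property
    def is_binary(self) -> bool:
        """True iff every internal vertex has exactly two children."""
        return all(len(k) in (0, 2) for k in self._children.values())

    def depth(self, v: str) -> int:
        return self._depth[v]

    # -- ancestry ----------------------------------------------------------

    def is_ancestor(self, u: str, v: str) -> bool:
        """True iff ``u`` is a *proper* ancestor of ``v``."""
        if u not in self._children or v not in self._children:
            raise InputError(f"vertex not in tree: {u if u not in self._children else v!r}")
        return u in self._ancestors[v]

    def are_comparable(self, u: str, v: str) -> bool:
        """True iff ``u`` and ``v`` are equal or ancestrally related."""
        return u == v or self.is_ancestor(u, v) or self.is_ancestor(v, u)

    def path_down(self, u: str, v: str) -> list[str]:
        """Vertices on the path from ``u`` down to ``v``, inclusive.

        ``u`` must be ``v`` or a proper ancestor of ``v``.
        """
        if u != v and not self.is_ancestor(u, v):
            raise InputError(f"{u!r} is not an ancestor of {v!r}")
        path = [v]
        while path[-1] != u:
            path.append(self._parent[path[-1]])
        path.reverse()
        return path

    def subtree(self, v: str) -> tuple[str, ...]:
        """Vertices of the subtree rooted at ``v`` (postorder slice order)."""
        out = []
        stack = [v]
        while stack:
            w = stack.pop()
            out.append(w)
            stack.extend(self._children[w])
        return tuple(out)

    # -- newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree({self.to_newick()!r})"


def parse_newick(text: str) -> RootedTree:
    """Parse a rooted newick string into a :class:`RootedTree`.

    Branch lengths and support values are accepted and discarded (the model
    is undated).  Leaf labels must be present and unique; internal labels
    are optional and kept when they do not collide with other names.
    Unnamed internal vertices receive deterministic document-order names.
    """
    if not text or not text.strip():
        raise ParseError("empty newick input")
    stripped = re.sub(r"\s+", "", text)
    bad = re.search(r"\(,|,,|,\)", stripped)
    if bad:
        raise ParseError(f"empty subtree at {bad.group(0)!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed newick: {exc}") from exc
    if dtree.seed_node is None:  # pragma: no cover - dendropy always sets it
        raise ParseError("empty newick input")

    leaf_labels: list[str] = []
    for nd in dtree.leaf_node_iter():
        if nd.taxon is None or not nd.taxon.label:
            raise ParseError("leaf without a label")
        leaf_labels.append(nd.taxon.label)
    if not leaf_labels:
        raise ParseError("tree has no leaves")
    dupes = {x for x in leaf_labels if leaf_labels.count(x) > 1}
    if dupes:
        raise ParseError(f"duplicate leaf label {sorted(dupes)[0]!r}")

    used = set(leaf_labels)
    generated: list[str] = []
    names: dict[int, str] = {}
    counter = 0
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            names[id(nd)] = nd.taxon.label
        else:
            label = nd.label
            if label and label not in used:
                names[id(nd)] = label
                used.add(label)
            else:
                while True:
                    auto = f"+n{counter}"
                    counter += 1
                    if auto not in used:
                        break
                names[id(nd)] = auto
                used.add(auto)
                generated.append(auto)

    children = {
        names[id(nd)]: tuple(names[id(c)] for c in nd.child_nodes())
        for nd in dtree.preorder_node_iter()
    }
    return RootedTree(names[id(dtree.seed_node)], children, generated)


def write_newick(tree: RootedTree) -> str:
    """Serialize a tree as newick; auto-generated internal names are omitted."""
    out = io.StringIO()

    def emit(v: str) -> None:
        kids = tree.children(v)
        if kids:
            out.write("(")
            for i, c in enumerate(kids):
                if i:
                    out.write(",")
                emit(c)
            out.write(")")
            if v not in tree._generated:
                out.write(v)
        else:
            out.write(v)

    emit(tree.root)
    out.write(";")
    return out.getvalue()


def postorder_edges(tree: RootedTree) -> tuple[str, ...]:
    """All edges of ``tree`` in postorder, each named by its terminus vertex.

    Children edges precede their parent's edge; the handle (the root's
    incoming edge) comes last.  The order is deterministic given the input
    child order.
    """
    return tree.postorder


def is_ancestor(tree: RootedTree, u: str, v: str) -> bool:
    """Strict ancestry predicate (module-level convenience)."""
    return tree.is_ancestor(u, v)


def are_comparable(tree: RootedTree, u: str, v: str) -> bool:
    return tree.are_comparable(u, v)


# -- leaf associations -----------------------------------------------------


@dataclass(frozen=True)
class LeafAssociation:
    """Tip data tying a gene tree to a species tree and to syntenic regions.

    ``phi`` maps each gene leaf to a species leaf (total, not necessarily
    injective or surjective); ``gamma`` maps each gene leaf to a positive
    integer syntenic region.  ``labels`` is the set L of actual syntenic
    regions, always taken to be the image of ``gamma``.
    """

    phi: Mapping[str, str]
    gamma: Mapping[str, int]
    labels: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", dict(self.phi))
        object.__setattr__(self, "gamma", dict(self.gamma))
        object.__setattr__(self, "labels", frozenset(self.gamma.values()))

    def validate(self, gene_tree: RootedTree, species_tree: RootedTree) -> None:
        sp_leaves = set(species_tree.leaves)
        for g in gene_tree.leaves:
            if g not in self.phi:
                raise InputError(f"gene leaf {g!r} missing from the species map")
            if g not in self.gamma:
                raise InputError(f"gene leaf {g!r} missing from the synteny map")
            if self.phi[g] not in sp_leaves:
                raise InputError(
                    f"gene leaf {g!r} mapped to {self.phi[g]!r}, "
                    "which is not a species leaf"
                )
        for g, lab in self.gamma.items():
            if not (isinstance(lab, int) and lab > 0):
                raise InputError(f"synteny region for {g!r} must be a positive integer")


def _read_two_columns(path_or_lines, what: str) -> dict[str, str]:
    if isinstance(path_or_lines, (str,)):
        with open(path_or_lines, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    out: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(
                f"{what}: line {lineno} has {len(parts)} column(s), expected 2"
            )
        key, value = parts[0].strip(), parts[1].strip()
        if key in out:
            raise InputError(f"{what}: duplicate row for gene leaf {key!r}")
        out[key] = value
    return out


def read_associations(
    leaf_map_table,
    synteny_table,
    gene_tree: RootedTree,
    species_tree: RootedTree,
) -> LeafAssociation:
    """Read the two tip tables (TSV paths or iterables of lines).

    Each table is two tab-separated columns; blank lines and lines starting
    with ``#`` are skipped.  The first table maps gene leaves to species
    leaves, the second maps gene leaves to positive-integer syntenic
    regions.  Every gene leaf must appear exactly once in each.
    """
    phi_raw = _read_two_columns(leaf_map_table, "leaf map")
    syn_raw = _read_two_columns(synteny_table, "synteny map")
    gamma: dict[str, int] = {}
    for g, v in syn_raw.items():
        try:
            lab = int(v)
        except ValueError:
            lab = 0
        if lab <= 0:
            raise InputError(
                f"synteny map: value {v!r} for {g!r} is not a positive integer"
            )
        gamma[g] = lab
    assoc = LeafAssociation(phi=phi_raw, gamma=gamma)
    assoc.validate(gene_tree, species_tree)
    return assoc
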