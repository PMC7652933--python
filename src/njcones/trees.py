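"""Unrooted binary trees carrying agglomeration orders.

Neighbor joining builds an unrooted binary tree by repeatedly merging two
"boughs" (vertices adjacent to the central node O) until only three remain.
Recording the step at which each internal node was created yields an
*agglomeration order*: a labeling of the ``n - 2`` internal nodes by
``{inf, 1, ..., n - 3}`` such that labels strictly decrease along every path
from the central node (the one labeled inf) to a leaf.  A binary tree endowed
with such an order is an *agglomerated tree*; it is a complete record of one
NJ execution up to the forced two-way tie at the last step.

Agglomerated trees are written in *ordered Newick* notation: an ordinary
Newick string in which every internal parenthesis is preceded by the step
index at which that node appeared, e.g. ``(3(c,1(a,b)),2(e,f),d)`` for a
6-taxon tree whose first cherry was ``(a,b)``.  The outermost parenthesis is
the central node and carries no label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

__all__ = [
    "AgglomeratedTree",
    "Topology",
    "Clade",
    "OrderedNewickError",
    "AgglomerationOrderError",
    "parse_ordered_newick",
    "serialize",
    "to_plain_newick",
    "strip_order",
    "enumerate_orders",
    "enumerate_topologies",
    "count_tree_shapes",
    "random_topology",
    "default_taxa",
]

_FORBIDDEN = set("(),;")


class OrderedNewickError(ValueError):
    """Malformed ordered-Newick string (parentheses, tokens, arity)."""


class AgglomerationOrderError(ValueError):
    """A labeling that is not a valid agglomeration order."""


@dataclass(frozen=True)
class Clade:
    """An internal node: ``label`` is the creation step (None at the center)."""

    label: Optional[int]
    children: tuple

    def __iter__(self):
        return iter(self.children)


#: A node of the rooted-at-center view: a taxon name or an internal clade.
Node = Union[str, Clade]


def _iter_leaves(node: Node) -> Iterator[str]:
    if isinstance(node, str):
        yield node
    else:
        for c in node.children:
            yield from _iter_leaves(c)


def _min_taxon(node: Node) -> str:
    return node if isinstance(node, str) else min(_min_taxon(c) for c in node.children)


def default_taxa(n: int) -> tuple[str, ...]:
    """Default taxon names: ``a, b, c, ...`` (``t1, t2, ...`` past 26)."""
    if n <= 26:
        return tuple("abcdefghijklmnopqrstuvwxyz"[:n])
    return tuple(f"t{i}" for i in range(1, n + 1))


class AgglomeratedTree:
    """An unrooted binary tree with an agglomeration order.

    Stored rooted at the central (inf) node, which has three children; every
    other internal node carries a step label from ``{1, ..., n - 3}`` and has
    two children.  Equality and hashing go through the canonical ordered
    Newick string, so two objects are equal iff they encode the same
    agglomerated tree.
    """

    __slots__ = ("root", "_canon")

    def __init__(self, root: Clade, validate: bool = True):
        self.root = root
        self._canon: Optional[str] = None
        if validate:
            self._validate()

    # -- basic views -------------------------------------------------------

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(_iter_leaves(self.root)))

    @property
    def n(self) -> int:
        return sum(1 for _ in _iter_leaves(self.root))

    def order_labels(self) -> set[int]:
        out: set[int] = set()

        def rec(node: Node) -> None:
            if isinstance(node, Clade):
                if node.label is not None:
                    out.add(node.label)
                for c in node.children:
                    rec(c)

        rec(self.root)
        return out

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        root = self.root
        if not isinstance(root, Clade) or root.label is not None:
            raise AgglomerationOrderError("central node must be unlabeled")
        if len(root.children) != 3:
            raise OrderedNewickError(
                f"central node must have 3 children, got {len(root.children)}"
            )
        labels: list[int] = []
        taxa: list[str] = []

        def rec(node: Node, parent_label: float) -> None:
            if isinstance(node, str):
                if not node or node[0].isdigit() or set(node) & _FORBIDDEN:
                    raise OrderedNewickError(f"invalid taxon name {node!r}")
                taxa.append(node)
                return
            if node.label is None:
                raise AgglomerationOrderError("only the central node may be unlabeled")
            if len(node.children) != 2:
                raise OrderedNewickError(
                    f"internal node {node.label} must have 2 children"
                )
            if not node.label < parent_label:
                raise AgglomerationOrderError(
                    f"label {node.label} does not decrease below its parent "
                    f"(parent label {parent_label})"
                )
            labels.append(node.label)
            for c in node.children:
                rec(c, node.label)

        for child in root.children:
            rec(child, float("inf"))
        if len(set(taxa)) != len(taxa):
            raise OrderedNewickError("duplicate taxon names")
        n = len(taxa)
        if n < 3:
            raise OrderedNewickError("need at least 3 taxa")
        expected = set(range(1, n - 2))
        if set(labels) != expected or len(labels) != len(expected):
            raise AgglomerationOrderError(
                f"order labels must be 1..{n - 3} each once, got {sorted(labels)}"
            )

    # -- equality through canonical form ----------------------------------

    def canonical(self) -> str:
        if self._canon is None:
            self._canon = serialize(self, canonical=True)
        return self._canon

    def __eq__(self, other) -> bool:
        return isinstance(other, AgglomeratedTree) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        return f"AgglomeratedTree({self.canonical()!r})"


# ---------------------------------------------------------------------------
# ordered Newick parsing / serialization
# ---------------------------------------------------------------------------


def parse_ordered_newick(s: str) -> AgglomeratedTree:
    """Parse an ordered Newick string into a validated :class:`AgglomeratedTree`.

    Grammar (whitespace ignored, optional trailing ``;``)::

        tree  := '(' item ',' item ',' item ')'
        item  := INT '(' item ',' item ')'   |   TAXON
        TAXON := any run without '(' ')' ',' ';' not starting with a digit

    Raises :class:`OrderedNewickError` on syntax/arity problems and
    :class:`AgglomerationOrderError` on an invalid order labeling.
    """
    text = "".join(s.split())
    if text.endswith(";"):
        text = text[:-1]
    pos = 0

    def error(msg: str) -> OrderedNewickError:
        return OrderedNewickError(f"{msg} at position {pos} in {s!r}")

    def parse_item() -> Node:
        nonlocal pos
        if pos >= len(text):
            raise error("unexpected end of string")
        ch = text[pos]
        if ch.isdigit():
            j = pos
            while j < len(text) and text[j].isdigit():
                j += 1
            if j >= len(text) or text[j] != "(":
                raise error("order label must be followed by '('")
            label = int(text[pos:j])
            pos = j
            children = parse_group()
            if len(children) != 2:
                raise error(f"labeled node {label} must join exactly 2 children")
            return Clade(label, tuple(children))
        if ch == "(":
            raise error("inner parenthesis lacks an order label")
        j = pos
        while j < len(text) and text[j] not in _FORBIDDEN:
            j += 1
        if j == pos:
            raise error("empty taxon name")
        name = text[pos:j]
        pos = j
        return name

    def parse_group() -> list[Node]:
        nonlocal pos
        assert text[pos] == "("
        pos += 1
        items = [parse_item()]
        while pos < len(text) and text[pos] == ",":
            pos += 1
            items.append(parse_item())
        if pos >= len(text) or text[pos] != ")":
            raise error("expected ')' or ','")
        pos += 1
        return items

    if not text.startswith("("):
        raise error("tree must start with '('")
    children = parse_group()
    if pos != len(text):
        raise error("trailing characters")
    if len(children) != 3:
        raise OrderedNewickError(
            f"outermost (central) node must have 3 children, got {len(children)}"
        )
    return AgglomeratedTree(Clade(None, tuple(children)))


def _node_string(node: Node, canonical: bool, with_labels: bool) -> str:
    if isinstance(node, str):
        return node
    children = list(node.children)
    if canonical:
        children.sort(key=_min_taxon)
    inner = ",".join(_node_string(c, canonical, with_labels) for c in children)
    label = str(node.label) if (with_labels and node.label is not None) else ""
    return f"{label}({inner})"


def serialize(t: AgglomeratedTree, canonical: bool = True) -> str:
    """Ordered Newick string for *t*.

    With ``canonical=True`` the children of every node are sorted by their
    smallest descendant taxon, which makes the string a unique key for the
    agglomerated tree (used for set-based counting).
    """
    return _node_string(t.root, canonical, with_labels=True)


def to_plain_newick(t: AgglomeratedTree, canonical: bool = True) -> str:
    """Plain Newick export (order labels dropped), ``;``-terminated."""
    return _node_string(t.root, canonical, with_labels=False) + ";"


# ---------------------------------------------------------------------------
# topologies
# ---------------------------------------------------------------------------


class Topology:
    """An unrooted binary tree on a leaf set, with order labels erased.

    Internally an adjacency map; leaves are strings, internal vertices any
    other hashable (ints by convention).  Equality and hashing use the split
    (bipartition) encoding, so they are independent of internal vertex names.
    """

    __slots__ = ("adjacency", "_splits")

    def __init__(self, adjacency: Mapping[object, Iterable[object]]):
        adj = {v: tuple(ns) for v, ns in adjacency.items()}
        self.adjacency: dict = adj
        self._splits: Optional[frozenset] = None
        self._validate()

    def _validate(self) -> None:
        adj = self.adjacency
        nedges = sum(len(ns) for ns in adj.values())
        if nedges % 2:
            raise ValueError("adjacency is not symmetric")
        for v, ns in adj.items():
            for u in ns:
                if v not in adj.get(u, ()):
                    raise ValueError("adjacency is not symmetric")
            deg = len(ns)
            if isinstance(v, str):
                if deg != 1:
                    raise ValueError(f"leaf {v!r} must have degree 1")
            elif deg != 3:
                raise ValueError(f"internal vertex {v!r} must have degree 3 (binary tree)")
        # connected with |E| = |V| - 1  =>  tree
        if adj:
            seen = set()
            stack = [next(iter(adj))]
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                stack.extend(adj[v])
            if len(seen) != len(adj):
                raise ValueError("graph is not connected")
            if nedges // 2 != len(adj) - 1:
                raise ValueError("graph has a cycle")

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(v for v in self.adjacency if isinstance(v, str)))

    @property
    def internal_vertices(self) -> list:
        return [v for v in self.adjacency if not isinstance(v, str)]

    @property
    def n(self) -> int:
        return len(self.leaves)

    def edges(self) -> list[tuple]:
        out = []
        seen = set()
        for v, ns in self.adjacency.items():
            for u in ns:
                if (u, v) in seen:
                    continue
                seen.add((v, u))
                out.append((v, u))
        return out

    def splits(self) -> frozenset:
        """Nontrivial splits, each encoded as the side avoiding the min leaf."""
        if self._splits is not None:
            return self._splits
        leaves = self.leaves
        if not leaves:
            return frozenset()
        ref = leaves[0]
        out = set()

        def side(v, parent) -> frozenset:
            acc = []
            stack = [(v, parent)]
            while stack:
                x, p = stack.pop()
                if isinstance(x, str):
                    acc.append(x)
                    continue
                for y in self.adjacency[x]:
                    if y is not p and y != p:
                        stack.append((y, x))
            return frozenset(acc)

        for v, u in self.edges():
            if isinstance(v, str) or isinstance(u, str):
                continue  # trivial split
            half = side(u, v)
            if ref in half:
                half = frozenset(leaves) - half
            out.add(half)
        self._splits = frozenset(out)
        return self._splits

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Topology)
            and self.leaves == other.leaves
            and self.splits() == other.splits()
        )

    def __hash__(self) -> int:
        return hash((self.leaves, self.splits()))

    def __repr__(self) -> str:
        return f"Topology(n={self.n}, splits={len(self.splits())})"


def strip_order(t: AgglomeratedTree) -> Topology:
    """Erase the agglomeration order, returning the bare unrooted topology."""
    adj: dict = {}
    counter = itertools.count()

    def add_edge(a, b) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def rec(node: Node):
        if isinstance(node, str):
            return node
        me = next(counter)
        adj.setdefault(me, [])
        for c in node.children:
            add_edge(me, rec(c))
        return me

    rec(t.root)
    return Topology(adj)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def enumerate_orders(top: Topology) -> list[AgglomeratedTree]:
    """All agglomeration orders that can be placed on *top* (brute force).

    Every internal vertex is tried as the central (inf) node; for each
    rooting, the decreasing-path condition makes valid labelings exactly the
    linear extensions of the rooted forest of internal nodes, enumerated by
    handing out labels ``n - 3, n - 4, ..., 1`` to any node whose parent is
    already labeled.  Exhaustive and duplicate-free; intended for small n.
    """
    n = top.n
    if n < 4:
        raise ValueError("agglomeration orders need n >= 4 taxa")
    results: list[AgglomeratedTree] = []
    for center in top.internal_vertices:
        # rooted children map
        children: dict = {}
        parent: dict = {center: None}
        stack = [center]
        while stack:
            v = stack.pop()
            kids = [u for u in top.adjacency[v] if u is not parent[v] and u != parent[v]]
            children[v] = kids
            for u in kids:
                parent[u] = v
                if not isinstance(u, str):
                    stack.append(u)
        internal_kids = {
            v: [u for u in kids if not isinstance(u, str)]
            for v, kids in children.items()
            if not isinstance(v, str)
        }
        label_of: dict = {}

        def assign(label: int, available: frozenset) -> None:
            if label == 0:
                results.append(_build_ordered(center, children, label_of))
                return
            for v in available:
                label_of[v] = label
                assign(label - 1, (available - {v}) | frozenset(internal_kids[v]))
                del label_of[v]

        assign(n - 3, frozenset(internal_kids[center]))
    return results


def _build_ordered(center, children, label_of) -> AgglomeratedTree:
    def rec(v) -> Node:
        if isinstance(v, str):
            return v
        return Clade(label_of.get(v), tuple(rec(u) for u in children[v]))

    root = Clade(None, tuple(rec(u) for u in children[center]))
    return AgglomeratedTree(root)


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[Topology]:
    """All ``(2n-5)!!`` labeled unrooted binary topologies, by leaf insertion."""
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    # adjacency with internal ids 0,1,...; edge list maintained alongside
    def rec(adj: dict, edges: list, next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield Topology(adj)
            return
        leaf = taxa[next_leaf]
        for a, b in list(edges):
            w = next_internal
            new_adj = {v: list(ns) for v, ns in adj.items()}
            new_adj[a].remove(b)
            new_adj[b].remove(a)
            new_adj[w] = [a, b, leaf]
            new_adj[a].append(w)
            new_adj[b].append(w)
            new_adj[leaf] = [w]
            new_edges = [e for e in edges if e != (a, b)]
            new_edges += [(a, w), (b, w), (leaf, w)]
            yield from rec(new_adj, new_edges, next_leaf + 1, next_internal + 1)

    base_adj: dict = {0: taxa[:3]}
    for t in taxa[:3]:
        base_adj[t] = [0]
    base_edges = [(t, 0) for t in taxa[:3]]
    yield from rec(base_adj, base_edges, 3, 1)


def random_topology(taxa: Sequence[str], rng) -> Topology:
    """A uniformly random labeled unrooted binary topology (random insertion).

    *rng* is a :class:`numpy.random.Generator` or anything accepted by
    ``numpy.random.default_rng``.
    """
    import numpy as _np

    if not isinstance(rng, _np.random.Generator):
        rng = _np.random.default_rng(rng)
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    adj: dict = {0: list(taxa[:3])}
    for t in taxa[:3]:
        adj[t] = [0]
    edges = [(t, 0) for t in taxa[:3]]
    nxt = 1
    for i in range(3, n):
        leaf = taxa[i]
        a, b = edges[int(rng.integers(len(edges)))]
        w = nxt
        nxt += 1
        adj[a].remove(b)
        adj[b].remove(a)
        adj[w] = [a, b, leaf]
        adj[a].append(w)
        adj[b].append(w)
        adj[leaf] = [w]
        edges = [e for e in edges if e != (a, b)] + [(a, w), (b, w), (leaf, w)]
    return Topology(adj)


def _shape_string(top: Topology) -> str:
    """Canonical unlabeled-shape string: min AHU encoding over all rootings."""

    def ahu(v, parent) -> str:
        if isinstance(v, str):
            return "L"
        subs = sorted(ahu(u, v) for u in top.adjacency[v] if u is not parent and u != parent)
        return "(" + ",".join(subs) + ")"

    return min(ahu(v, None) for v in top.internal_vertices)


def count_tree_shapes(n: int) -> int:
    """Number of distinct unlabeled shapes among unrooted binary trees on n taxa."""
    shapes = {_shape_string(t) for t in enumerate_topologies(default_taxa(n))}
    return len(shapes)
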