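"""Rooted binary trees with the engine's node-numbering contract.

Tips are numbered ``0..n-1`` in taxon order and internal nodes
``n..2n-2`` in postorder, so the root is always ``2n-2``.  Branch
lengths (expected substitutions per site) are attached to the node
*below* each edge; the root carries none.

Newick input may be rooted (bifurcating root) or unrooted (trifurcating
root).  Unrooted trees are rooted deterministically on the first-listed
child edge, splitting its length equally — for reversible models the
likelihood is invariant to root placement, so the choice only needs to
be reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError

__all__ = ["Tree", "read_newick", "write_newick", "unrooted_edges", "root_on_edge"]


@dataclass(frozen=True)
class Tree:
    """Immutable rooted binary tree.

    Attributes
    ----------
    taxon_names : tuple of str
        Tip ``i`` carries ``taxon_names[i]``.
    parent : ndarray (2n-1,)
        Parent node id; -1 for the root.
    children : ndarray (2n-1, 2)
        Child ids for internal nodes, (-1, -1) rows for tips.
    lengths : ndarray (2n-1,)
        Length of the edge above each node; 0 for the root.
    """

    taxon_names: tuple[str, ...]
    parent: np.ndarray
    children: np.ndarray
    lengths: np.ndarray

    @property
    def tip_count(self) -> int:
        return len(self.taxon_names)

    @property
    def node_count(self) -> int:
        return 2 * self.tip_count - 1

    @property
    def root(self) -> int:
        return self.node_count - 1

    def is_tip(self, node: int) -> bool:
        return node < self.tip_count

    def postorder_internal(self) -> list[int]:
        """Internal node ids, children before parents, left subtree first."""
        order: list[int] = []
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if self.is_tip(node):
                continue
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                c1, c2 = self.children[node - 0]
                stack.append((int(c2), False))
                stack.append((int(c1), False))
        return order

    def validate(self) -> None:
        n = self.tip_count
        if n < 2:
            raise ValidationError("a tree needs at least two tips")
        internal = [v for v in range(self.node_count) if not self.is_tip(v)]
        if len(internal) != n - 1:
            raise ValidationError("rooted binary tree must have n-1 internal nodes")
        for v in internal:
            c1, c2 = self.children[v]
            if c1 < 0 or c2 < 0:
                raise ValidationError(f"internal node {v} is not binary")
        if np.any(self.lengths < 0):
            raise ValidationError("negative branch length")


class _Node:
    __slots__ = ("name", "length", "children")

    def __init__(self):
        self.name: str | None = None
        self.length: float | None = None
        self.children: list[_Node] = []


def _tokenize(text: str):
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "(),:;":
            yield ch
            i += 1
        else:
            j = i
            while j < n and text[j] not in "(),:;" and not text[j].isspace():
                j += 1
            yield text[i:j]
            i = j


def _parse_nested(text: str) -> _Node:
    tokens = list(_tokenize(text))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def clade() -> _Node:
        node = _Node()
        if peek() == "(":
            take()
            node.children.append(clade())
            while peek() == ",":
                take()
                node.children.append(clade())
            if take() != ")":
                raise ParseError("unbalanced parentheses in Newick string")
            if peek() not in ("(", ")", ",", ":", ";", None):
                node.name = take()
        else:
            tok = take()
            if tok is None or tok in "(),:;":
                raise ParseError(f"unexpected token {tok!r} in Newick string")
            node.name = tok
        if peek() == ":":
            take()
            tok = take()
            try:
                node.length = float(tok)
            except (TypeError, ValueError):
                raise ParseError(f"bad branch length {tok!r}") from None
        return node

    root = clade()
    if peek() == ";":
        take()
    if pos != len(tokens):
        raise ParseError("trailing characters after Newick tree")
    return root


def _build(root: _Node, taxon_order) -> Tree:
    tips: list[_Node] = []
    internals: list[_Node] = []

    def collect(node: _Node):
        if node.children:
            for ch in node.children:
                collect(ch)
            internals.append(node)
        else:
            if not node.name:
                raise ParseError("unnamed tip in Newick string")
            tips.append(node)

    collect(root)
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        raise ParseError("duplicate tip names in tree")
    if taxon_order is not None:
        index = {name: i for i, name in enumerate(taxon_order)}
        missing = [nm for nm in names if nm not in index]
        if missing:
            raise ParseError(f"tree taxa not in alignment: {missing}")
        if len(names) != len(taxon_order):
            raise ParseError("tree and alignment have different taxon sets")
        order = index
        taxon_names = tuple(taxon_order)
    else:
        order = {name: i for i, name in enumerate(names)}
        taxon_names = tuple(names)

    n = len(names)
    ids: dict[int, int] = {}
    for t in tips:
        ids[id(t)] = order[t.name]
    for k, v in enumerate(internals):  # collect() appended in postorder
        ids[id(v)] = n + k

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    lengths = np.zeros(2 * n - 1)

    def fill(node: _Node):
        vid = ids[id(node)]
        if node.length is not None:
            lengths[vid] = node.length
        for a, ch in enumerate(node.children):
            cid = ids[id(ch)]
            parent[cid] = vid
            children[vid, a] = cid
            fill(ch)

    missing_lengths = any(
        nd.length is None for nd in tips + internals if nd is not root
    )
    if missing_lengths:
        warnings.warn("missing branch lengths default to 0", stacklevel=3)
    fill(root)
    tree = Tree(taxon_names, parent, children, lengths)
    tree.validate()
    return tree


def read_newick(source: str | Path, taxon_order=None) -> Tree:
    """Parse a Newick string or file into a rooted :class:`Tree`.

    A trifurcating (unrooted) root is resolved by inserting the root on
    the first-listed child edge at its midpoint.  ``taxon_order`` maps
    tip names to tip ids (e.g. alignment taxon order); without it, tips
    are numbered in order of appearance.
    """
    text = str(source)
    if "(" not in text:
        path = Path(text)
        if not path.exists():
            raise ParseError(f"no such tree file: {text}")
        text = path.read_text()
    nested = _parse_nested(text)
    if len(nested.children) == 3:
        first = nested.children[0]
        rest = _Node()
        rest.children = nested.children[1:]
        half = (first.length or 0.0) / 2.0
        first.length = half
        rest.length = half
        root = _Node()
        root.children = [first, rest]
        nested = root
    elif len(nested.children) != 2:
        raise ParseError(
            f"root must have 2 or 3 children, found {len(nested.children)}"
        )
    return _build(nested, taxon_order)


def write_newick(tree: Tree) -> str:
    """Serialize with full double precision (round-trips exactly)."""

    def fmt(node: int) -> str:
        if tree.is_tip(node):
            label = tree.taxon_names[node]
        else:
            c1, c2 = tree.children[node]
            label = f"({fmt(int(c1))},{fmt(int(c2))})"
        if node == tree.root:
            return label
        return f"{label}:{tree.lengths[node]:.17g}"

    return fmt(tree.root) + ";"


def unrooted_edges(tree: Tree):
    """Adjacency of the unrooted tree plus a deterministic edge list.

    The root (a degree-2 vertex) is suppressed: its two incident edges
    fuse into one with summed length.  Edges are returned sorted by
    ``(min_id, max_id)`` using the input tree's node ids, which makes
    edge indices — and any tie-breaking on them — reproducible.
    """
    adj: dict[int, list[tuple[int, float]]] = {}

    def add(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    root = tree.root
    rc1, rc2 = (int(c) for c in tree.children[root])
    for v in range(tree.node_count):
        p = int(tree.parent[v])
        if p < 0 or p == root:
            continue
        add(v, p, float(tree.lengths[v]))
    add(rc1, rc2, float(tree.lengths[rc1] + tree.lengths[rc2]))
    edges = sorted(
        {(min(u, v), max(u, v)) for u in adj for v, _ in adj[u]}
    )
    lengths = {}
    for u in adj:
        for v, w in adj[u]:
            lengths[(min(u, v), max(u, v))] = w
    return adj, [(u, v, lengths[(u, v)]) for u, v in edges]


def root_on_edge(tree: Tree, edge: tuple[int, int], fraction: float = 0.5) -> Tree:
    """Re-root at a point on the given unrooted edge.

    All tip-to-tip path lengths are preserved, so for reversible models
    the likelihood is unchanged.  ``fraction`` splits the edge length
    between the ``u`` side and the ``v`` side.
    """
    adj, edges = unrooted_edges(tree)
    u, v = min(edge), max(edge)
    length = None
    for a, b, w in edges:
        if (a, b) == (u, v):
            length = w
            break
    if length is None:
        raise ValidationError(f"({u}, {v}) is not an edge of the unrooted tree")

    def subtree(node: int, came_from: int) -> _Node:
        nd = _Node()
        kids = [(nbr, w) for nbr, w in adj[node] if nbr != came_from]
        if not kids:
            nd.name = tree.taxon_names[node]
        else:
            for nbr, w in sorted(kids):
                ch = subtree(nbr, node)
                ch.length = w
                nd.children.append(ch)
        return nd

    left = subtree(u, v)
    left.length = length * fraction
    right = subtree(v, u)
    right.length = length * (1.0 - fraction)
    root = _Node()
    root.children = [left, right]
    return _build(root, tree.taxon_names)
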