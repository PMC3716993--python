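"""Rooted weighted phylogenetic trees with nested taxa.

The object of study is a rooted tree whose arcs carry strictly positive
weights and some of whose nodes are bijectively labeled by a taxon set S.
Every leaf must be labeled, and every elementary (out-degree-1) node must
be labeled except possibly the root.  Labeled internal nodes are *nested
taxa*.  Unweighted trees are identified with weight-1 trees.

Trees are built from :class:`PhyloNode` objects and wrapped in a validated
:class:`PhyloTree`.  Newick is the external format: internal node labels
denote nested taxa, missing branch lengths default to 1, and an outer
``(X);`` wrapper with an unlabeled root of out-degree 1 is permitted.
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "TreeError",
    "parse_newick",
    "write_newick",
    "contract_arc",
    "replace_subtree",
    "taxon_sort_key",
]

#: significant digits used when serializing branch lengths
LENGTH_PRECISION = 12

#: default tolerance for comparing real-valued arc weights
WEIGHT_TOL = 1e-9


class TreeError(ValueError):
    """Raised when a tree violates the phylogenetic-tree invariants."""


def taxon_sort_key(label: str):
    """Sort key for taxa: numeric when every use is an integer literal,
    lexicographic otherwise.  Applied via ``sorted(labels, key=...)`` only
    after checking all labels jointly; see :func:`sort_taxa`."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


def sort_taxa(labels) -> list[str]:
    """Canonical taxon order: numeric if all labels parse as integers,
    else plain lexicographic."""
    labels = list(labels)
    try:
        return sorted(labels, key=lambda s: int(s))
    except ValueError:
        return sorted(labels)


class PhyloNode:
    """A node of a rooted tree: optional taxon label, children, and the
    weight of the incoming arc (``None`` for the root)."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None,
                 children: list["PhyloNode"] | None = None):
        self.label = label
        self.length = length
        self.children: list[PhyloNode] = children if children is not None else []
        self.parent: PhyloNode | None = None
        for c in self.children:
            c.parent = self

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["PhyloNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["PhyloNode"]:
        out: list[PhyloNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def copy(self) -> "PhyloNode":
        new = PhyloNode(self.label, self.length)
        for c in self.children:
            new.add_child(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloNode(label={self.label!r}, length={self.length}, nc={len(self.children)})"


class PhyloTree:
    """A validated rooted weighted phylogenetic tree with nested taxa.

    Parameters
    ----------
    root:
        Root node of a :class:`PhyloNode` structure.  The structure is
        owned by the tree; callers should pass a fresh copy if they keep
        a reference.

    Raises
    ------
    TreeError
        If a leaf or a non-root elementary node is unlabeled, labels are
        duplicated, or an arc weight is not strictly positive.
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        self._validate()
        self.taxa: tuple[str, ...] = tuple(
            sort_taxa(n.label for n in root.preorder() if n.label is not None))
        self._key = None

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        self.root.parent = None
        for node in self.root.preorder():
            if node is self.root:
                if node.length is not None:
                    raise TreeError("root must not carry an incoming arc weight")
            else:
                w = 1.0 if node.length is None else node.length
                if not w > 0:
                    raise TreeError(f"non-positive arc weight {node.length!r}")
                node.length = float(w)
            if node.label is not None:
                if node.label in seen:
                    raise TreeError(f"duplicate taxon label {node.label!r}")
                seen.add(node.label)
            else:
                if node.is_leaf:
                    raise TreeError("unlabeled leaf")
                if len(node.children) == 1 and node is not self.root:
                    raise TreeError("unlabeled non-root elementary node")
        if not seen:
            raise TreeError("tree has no taxa")

    # -- basic queries ------------------------------------------------

    @property
    def n(self) -> int:
        """Number of taxa."""
        return len(self.taxa)

    def node_of(self, taxon: str) -> PhyloNode:
        for node in self.root.preorder():
            if node.label == taxon:
                return node
        raise KeyError(f"unknown taxon {taxon!r}")

    def depths(self) -> dict[PhyloNode, float]:
        """Depth of every node: weighted distance from the root, in one
        preorder traversal."""
        depth: dict[PhyloNode, float] = {self.root: 0.0}
        for node in self.root.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
        return depth

    def taxon_depths(self) -> dict[str, float]:
        d = self.depths()
        return {n.label: d[n] for n in self.root.preorder() if n.label is not None}

    def lca(self, i: str, j: str) -> PhyloNode:
        """Lowest common ancestor of the nodes labeled *i* and *j*
        (``lca(i, i)`` is the node of *i* itself)."""
        a, b = self.node_of(i), self.node_of(j)
        ancestors = set()
        node = a
        while node is not None:
            ancestors.add(id(node))
            node = node.parent
        node = b
        while node is not None:
            if id(node) in ancestors:
                return node
            node = node.parent
        raise TreeError("disconnected tree")  # unreachable on a valid tree

    def descendant_taxa(self, node: PhyloNode) -> set[str]:
        """Taxa labeling *node* or any of its descendants."""
        return {n.label for n in node.preorder() if n.label is not None}

    def is_weighted(self) -> bool:
        """True if any arc weight differs from 1 (the unweighted default)."""
        return any(n.length != 1.0 for n in self.root.preorder() if n is not self.root)

    def has_nested_taxa(self) -> bool:
        return any(n.label is not None and not n.is_leaf for n in self.root.preorder())

    # -- canonical form -----------------------------------------------

    def canonical_key(self):
        """An opaque, totally ordered value equal for two trees on the same
        taxon set iff they are isomorphic (labels and arc weights preserved).

        Built by recursive serialization of ``(label, weight, sorted
        children keys)``; child order is irrelevant by construction.
        """
        if self._key is None:
            self._key = _node_key(self.root)
        return self._key

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())

    def __repr__(self) -> str:
        return f"PhyloTree({write_newick(self)!r})"


def _node_key(node: PhyloNode):
    label = "" if node.label is None else node.label
    length = 0.0 if node.length is None else round(node.length, 12)
    return (label, length, tuple(sorted(_node_key(c) for c in node.children)))


# -- Newick I/O -------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Internal node labels denote nested taxa; missing branch lengths
    default to 1; quoted labels are supported; bracketed comment blocks
    are rejected.  An outer wrapper with a single child and no root label
    yields an unlabeled elementary root.
    """
    if _has_comment(text):
        raise TreeError("Newick comment blocks are not supported")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeError(f"invalid Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    return PhyloTree(root)


def _has_comment(text: str) -> bool:
    quoted = False
    for ch in text:
        if ch == "'":
            quoted = not quoted
        elif ch == "[" and not quoted:
            return True
    return False


def _from_dendropy(dnode) -> PhyloNode:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = PhyloNode(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def write_newick(tree: PhyloTree) -> str:
    """Serialize to canonical Newick: children sorted by canonical key so
    the output is deterministic; branch lengths emitted only when some
    weight differs from 1."""
    with_lengths = tree.is_weighted()
    buf = io.StringIO()
    _write_node(tree.root, buf, with_lengths, is_root=True)
    buf.write(";")
    return buf.getvalue()


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;,='\t\n ") or label == "":
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(node: PhyloNode, buf, with_lengths: bool, is_root: bool = False) -> None:
    if node.children:
        buf.write("(")
        for k, child in enumerate(sorted(node.children, key=_node_key)):
            if k:
                buf.write(",")
            _write_node(child, buf, with_lengths)
        buf.write(")")
    if node.label is not None:
        buf.write(_quote_label(node.label))
    if with_lengths and not is_root:
        buf.write(":%.*g" % (LENGTH_PRECISION, node.length))


# -- structural edits -------------------------------------------------


def contract_arc(tree: PhyloTree, v: PhyloNode) -> PhyloTree:
    """Contract the arc ``(parent(v), v)``: remove *v*, transfer its label
    to its parent if it had one, and re-attach its children to the parent.

    This is the Robinson-Foulds alpha-operation.  Either endpoint must be
    unlabeled, and the contraction must not create an unlabeled non-root
    elementary node.  Returns a new tree; *tree* is unmodified.
    """
    if v is tree.root or v.parent is None:
        raise TreeError("cannot contract: node has no incoming arc")
    u = v.parent
    if u.label is not None and v.label is not None:
        raise TreeError("cannot contract an arc with both endpoints labeled")
    new_root, mapping = _copy_with_map(tree.root)
    u2, v2 = mapping[id(u)], mapping[id(v)]
    u2.children.remove(v2)
    if v2.label is not None:
        u2.label = v2.label
    for child in v2.children:
        u2.add_child(child)
    try:
        return PhyloTree(new_root)
    except TreeError as exc:
        raise TreeError(f"contraction yields an invalid tree: {exc}") from exc


def replace_subtree(tree: PhyloTree, node: PhyloNode, sub: PhyloTree) -> PhyloTree:
    """Swap the subtree rooted at *node* for *sub*, keeping the incoming
    arc weight.  The taxon set of *sub* must equal the descendant-taxon
    set of *node*; everything outside the subtree is untouched."""
    if tree.descendant_taxa(node) != set(sub.taxa):
        raise TreeError("replacement subtree must carry the same taxon set")
    new_sub = sub.root.copy()
    if node is tree.root:
        return PhyloTree(new_sub)
    new_root, mapping = _copy_with_map(tree.root)
    node2 = mapping[id(node)]
    parent = node2.parent
    idx = parent.children.index(node2)
    new_sub.length = node2.length
    new_sub.parent = parent
    parent.children[idx] = new_sub
    return PhyloTree(new_root)


def _copy_with_map(root: PhyloNode):
    """Deep copy returning also a map id(original) -> copy."""
    mapping: dict[int, PhyloNode] = {}

    def rec(node: PhyloNode) -> PhyloNode:
        new = PhyloNode(node.label, node.length)
        mapping[id(node)] = new
        for c in node.children:
            new.add_child(rec(c))
        return new

    return rec(root), mapping
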