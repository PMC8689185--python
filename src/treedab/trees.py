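"""Feature hierarchies and their ancestor-matrix representation.

A hierarchy is a rooted (generally multifurcating) tree whose ``p`` leaves are
the features of a count table — genera, ASVs, cell types.  The model never
uses branch lengths: only the topology and, per node, the number of leaves in
its subtree matter.  The tree is summarised by a binary ancestor matrix
``A`` of shape ``(p, v)`` with one column per node (leaves first, internal
nodes in post-order with the root last); ``A[j, k] = 1`` iff node ``k`` is
leaf ``j`` itself or one of its ancestors.  Multiplying node-level effects by
``A.T`` propagates them down to the leaves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio


class _Node:
    """Tree node; a leaf iff ``children`` is empty."""

    __slots__ = ("name", "children", "parent")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = list(children) if children else []
        self.parent = None
        for c in self.children:
            c.parent = self

    def add(self, child: "_Node") -> "_Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "_Node":
        return _Node(self.name, [c.copy() for c in self.children])


@dataclass
class AncestorMatrix:
    """Binary leaf x node ancestry indicator with subtree leaf counts.

    Attributes
    ----------
    A : ndarray of shape (p, v)
        ``A[j, k] = 1`` iff node ``k`` equals leaf ``j`` or is an ancestor of
        it.  The first ``p`` columns are the leaves in leaf order (an identity
        block); the remaining columns are internal nodes in post-order, root
        last.
    column_names : list of str
        Node name per column.
    leaf_counts : ndarray of shape (v,)
        ``leaf_counts[k]`` is the number of leaves in the subtree of node
        ``k`` (1 for leaves, ``p`` for the root).
    """

    A: np.ndarray
    column_names: list = field(default_factory=list)
    leaf_counts: np.ndarray = None

    @property
    def n_leaves(self) -> int:
        return self.A.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.A.shape[1]


class Hierarchy:
    """Rooted multifurcating tree over the features of a count table."""

    def __init__(self, root: _Node):
        self._root = root
        self._index()
        names = self.leaf_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")

    def _index(self) -> None:
        leaves = []
        internal = []

        def post(node):
            if node.is_leaf:
                leaves.append(node)
            else:
                for c in node.children:
                    post(c)
                internal.append(node)

        post(self._root)
        self._leaves = leaves
        self._internal = internal  # post-order, root last
        self._assign_internal_names()

    def _assign_internal_names(self) -> None:
        taken = {lf.name for lf in self._leaves}
        taken.update(n.name for n in self._internal if n.name)
        k = 0
        for node in self._internal:
            if not node.name:
                k += 1
                name = f"node{k}"
                while name in taken:
                    k += 1
                    name = f"node{k}"
                node.name = name
                taken.add(name)

    # -- basic structure -------------------------------------------------

    @property
    def root(self) -> _Node:
        return self._root

    @property
    def leaves(self) -> list:
        return list(self._leaves)

    @property
    def leaf_names(self) -> list:
        return [lf.name for lf in self._leaves]

    @property
    def internal_nodes(self) -> list:
        return list(self._internal)

    @property
    def node_names(self) -> list:
        """Column order of the ancestor matrix: leaves, then internal post-order."""
        return self.leaf_names + [n.name for n in self._internal]

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def n_internal(self) -> int:
        return len(self._internal)

    @property
    def n_nodes(self) -> int:
        return self.n_leaves + self.n_internal

    @property
    def depth(self) -> int:
        """Maximum number of edges from the root to any leaf."""

        def d(node):
            return 0 if node.is_leaf else 1 + max(d(c) for c in node.children)

        return d(self._root)

    def copy(self) -> "Hierarchy":
        return Hierarchy(self._root.copy())

    def subtree_leaves(self, name: str) -> list:
        """Leaf names contained in the subtree rooted at node ``name``."""
        node = self._find(name)
        out = []

        def collect(n):
            if n.is_leaf:
                out.append(n.name)
            else:
                for c in n.children:
                    collect(c)

        collect(node)
        return out

    def _find(self, name: str) -> _Node:
        for n in self._leaves + self._internal:
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def ancestor_names(self, leaf_name: str) -> list:
        """Names of the strict ancestors of a leaf, nearest first, root last."""
        node = self._find(leaf_name)
        out = []
        while node.parent is not None:
            node = node.parent
            out.append(node.name)
        return out

    # -- normalisation ---------------------------------------------------

    def normalize(self) -> "Hierarchy":
        """Remove singular nodes (internal nodes with exactly one child).

        A single-child node carries no aggregation information: its effect
        would propagate to exactly the same leaves as its child's.  Chains
        are collapsed fully; the operation is idempotent and preserves the
        leaf set and leaf order.
        """
        root = self._root.copy()
        while len(root.children) == 1 and not root.is_leaf:
            root = root.children[0]
            root.parent = None

        def collapse(node):
            new_children = []
            for c in node.children:
                while len(c.children) == 1:
                    c = c.children[0]
                collapse(c)
                c.parent = node
                new_children.append(c)
            node.children = new_children

        collapse(root)
        return Hierarchy(root)

    # -- ancestor matrix -------------------------------------------------

    def ancestor_matrix(self) -> AncestorMatrix:
        """Build the binary ancestor matrix and subtree leaf counts."""
        p, t = self.n_leaves, self.n_internal
        v = p + t
        col_of = {lf.name: j for j, lf in enumerate(self._leaves)}
        for i, node in enumerate(self._internal):
            col_of[node.name] = p + i
        A = np.zeros((p, v), dtype=np.int8)
        for j, lf in enumerate(self._leaves):
            A[j, j] = 1
            for anc in self.ancestor_names(lf.name):
                A[j, col_of[anc]] = 1
        leaf_counts = A.sum(axis=0).astype(np.int64)
        return AncestorMatrix(A=A, column_names=self.node_names, leaf_counts=leaf_counts)

    # -- serialisation ---------------------------------------------------

    def to_newick(self, include_internal_names: bool = True) -> str:
        def fmt(node):
            if node.is_leaf:
                return node.name
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name if include_internal_names and node.name else ""
            return f"({inner}){label}"

        return fmt(self._root) + ";"

    def __repr__(self) -> str:
        return (
            f"Hierarchy(p={self.n_leaves}, internal={self.n_internal}, "
            f"depth={self.depth})"
        )


def parse_newick(text: str) -> Hierarchy:
    """Parse a newick string into a :class:`Hierarchy`.

    Branch lengths, if present, are tolerated and discarded; only the
    topology is kept.  Leaf order follows the left-to-right order of the
    newick string.

    Raises
    ------
    ValueError
        If the string is malformed (message carries the parser's position
        information) or leaf labels are duplicated.
    """
    try:
        sk = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError
        raise ValueError(f"malformed newick: {exc}") from exc

    def convert(sknode):
        if sknode.is_tip():
            if sknode.name is None:
                raise ValueError("malformed newick: unlabeled leaf")
            return _Node(sknode.name)
        return _Node(sknode.name, [convert(c) for c in sknode.children])

    return Hierarchy(convert(sk))


def tree_from_taxonomy(
    table: pd.DataFrame,
    feature_column: str | None = None,
    on_unknown: str = "raise",
) -> Hierarchy:
    """Build a hierarchy from a taxonomy-rank table (root-most rank first).

    Each row is one feature; the rank columns (e.g. Kingdom ... Genus) are
    read left to right and every distinct observed lineage prefix becomes an
    internal node.  Each feature leaf is attached under its deepest known
    rank.  Features whose terminal rank is missing or empty are rejected (or
    dropped with ``on_unknown="drop"``), mirroring analyses restricted to
    features with a known terminal classification.  Singular chains are
    collapsed via :meth:`Hierarchy.normalize`.
    """
    if feature_column is not None:
        table = table.set_index(feature_column)
    ranks = list(table.columns)
    if not ranks:
        raise ValueError("taxonomy table needs at least one rank column")

    terminal = table[ranks[-1]]
    bad = table.index[terminal.isna() | (terminal.astype(str).str.strip() == "")]
    if len(bad):
        if on_unknown == "drop":
            table = table.drop(index=bad)
        else:
            raise ValueError(
                "features with unknown terminal rank: " + ", ".join(map(str, bad))
            )
    if not table.index.is_unique:
        raise ValueError("duplicate feature identifiers in taxonomy table")

    root = _Node("root")
    prefix_node = {(): root}
    for feat, row in table.iterrows():
        prefix = ()
        parent = root
        for rank in ranks:
            val = row[rank]
            if pd.isna(val) or str(val).strip() == "":
                break
            prefix = prefix + (str(val),)
            node = prefix_node.get(prefix)
            if node is None:
                node = parent.add(_Node("/".join(prefix)))
                prefix_node[prefix] = node
            parent = node
        parent.add(_Node(str(feat)))

    return Hierarchy(root).normalize()
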