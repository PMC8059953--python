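"""Rooted time-trees with absolute node ages (Ma) and branch durations (Myr).

The internal tree class is deliberately small: it exists so that the dating,
simulation and likelihood code can manipulate ages and branch durations as
plain arrays.  Newick parsing and writing are delegated to :mod:`dendropy`.

Conventions
-----------
* Ages are in Ma before present; larger = older.  Branch durations are in Myr
  and equal ``parent.age - child.age``.
* A "branch" is identified by its child node; the root carries no branch.
* Polytomies are representable (and are resolved by
  :func:`morphodyn.timescale.resolve_polytomies`); dated trees are required to
  be strictly binary with strictly positive durations.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy
import numpy as np


class Node:
    __slots__ = ("parent", "children", "length", "age", "label", "index")

    def __init__(self, label: str | None = None, length: float | None = None,
                 age: float | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length          # duration of the branch above, Myr
        self.age = age                # absolute age, Ma
        self.label = label
        self.index: int | None = None  # postorder index, set by Tree.reindex()

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf() else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} age={self.age} len={self.length}>"


class Tree:
    """A rooted tree; when node ages are set this is a time-tree."""

    def __init__(self, root: Node):
        self.root = root
        self.reindex()

    # ------------------------------------------------------------------
    # construction / IO
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "Tree":
        """Parse a Newick string or file path (branch lengths = durations)."""
        if "(" not in source:  # looks like a path
            with open(source) as fh:
                source = fh.read()
        dtree = dendropy.Tree.get(data=source, schema="newick",
                                  preserve_underscores=True)

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        root.length = None
        return cls(root)

    def to_newick(self) -> str:
        """Serialize with branch lengths = durations (Myr), via dendropy."""
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def convert(node: Node, dnode) -> None:
            if node.is_leaf():
                taxon = taxa.new_taxon(node.label or f"t{node.index}")
                dnode.taxon = taxon
            elif node.label:
                dnode.label = node.label
            dnode.edge.length = node.length
            for child in node.children:
                dchild = dnode.new_child()
                convert(child, dchild)

        convert(self.root, dtree.seed_node)
        return dtree.as_string(schema="newick", suppress_rooting=True,
                               unquoted_underscores=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------------
    # traversal & lookup
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def reindex(self) -> list[Node]:
        """Assign postorder indices (children before parents, root last)."""
        nodes = list(self.postorder())
        for i, node in enumerate(nodes):
            node.index = i
        return nodes

    def find(self, label: str) -> Node:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        want = set(labels)
        if not want:
            raise ValueError("mrca of an empty label set")
        below: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf():
                below[node] = {node.label} & want
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if below[node] == want:
                return node
        raise KeyError(f"labels not all present: {sorted(want)}")

    def clade_leaf_labels(self, node: Node) -> frozenset:
        labels = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                labels.append(n.label)
            stack.extend(n.children)
        return frozenset(labels)

    def subtree_nodes(self, node: Node) -> list[Node]:
        """All nodes of the clade rooted at ``node``, node itself included."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def bipartitions(self) -> dict[frozenset, Node]:
        """Map clade tip-label set -> node, for every non-root node."""
        out: dict[frozenset, Node] = {}
        below: dict[Node, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf():
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node is not self.root:
                out[below[node]] = node
        return out

    # ------------------------------------------------------------------
    # ages / durations
    # ------------------------------------------------------------------
    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def update_lengths_from_ages(self) -> None:
        for node in self.postorder():
            if node.parent is not None:
                node.length = node.parent.age - node.age
        self.root.length = None

    def update_ages_from_lengths(self, tip_ages: dict[str, float] | None = None) -> None:
        """Set absolute ages from branch lengths.

        With ``tip_ages`` given, the root age is chosen as
        ``max(depth(tip) + age(tip))``; otherwise the deepest tip is placed at
        age 0 (extant).  For internally consistent trees both give the same
        result.
        """
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[node] = depth[node.parent] + (node.length or 0.0)
        if tip_ages is None:
            root_age = max(depth[leaf] for leaf in self.leaves())
        else:
            root_age = max(depth[leaf] + tip_ages[leaf.label] for leaf in self.leaves())
        for node in self.postorder():
            node.age = root_age - depth[node]

    def validate_dated(self, tol: float = 1e-9) -> None:
        """Assert strictly positive durations and consistent ages."""
        for node in self.postorder():
            if node.parent is not None:
                if node.age is None or node.parent.age is None:
                    raise ValueError("tree is not fully dated")
                if node.parent.age - node.age <= tol:
                    raise ValueError(
                        f"non-positive branch duration above node {node.label!r}"
                    )

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(label=node.label, length=node.length, age=node.age)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {self.n_leaves} tips, root age {self.root.age}>"


# ----------------------------------------------------------------------
# array views for numerical kernels
# ----------------------------------------------------------------------
def tree_arrays(tree: Tree):
    """Postorder array view of a binary dated tree.

    Returns ``(nodes, lengths, left, right, tip_index)`` where ``nodes`` is the
    postorder node list, ``lengths[i]`` the branch duration above node i
    (0 for the root), ``left``/``right`` the child indices of internal nodes
    in postorder-of-internals order, and ``tip_index`` maps tip label -> index.
    """
    if not tree.is_binary():
        raise ValueError("array view requires a strictly binary tree")
    nodes = tree.reindex()
    m = len(nodes)
    lengths = np.zeros(m)
    for node in nodes:
        lengths[node.index] = node.length if node.parent is not None else 0.0
    internals = [n for n in nodes if not n.is_leaf()]
    left = np.array([n.children[0].index for n in internals], dtype=np.int64)
    right = np.array([n.children[1].index for n in internals], dtype=np.int64)
    internal_idx = np.array([n.index for n in internals], dtype=np.int64)
    tip_index = {n.label: n.index for n in nodes if n.is_leaf()}
    return nodes, lengths, left, right, internal_idx, tip_index
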