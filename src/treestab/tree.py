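"""Leaf-labelled binary trees: construction, rerooting, splits, Newick I/O.

The same lightweight structure serves both unrooted neighbor-joining output
(root node of degree 3) and rooted trees (root of degree 2, as produced by
outgroup rooting or used by the sequence simulator). Branch lengths live on
the child end of each edge, in expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import dendropy

from .errors import InputError, LabelLookupError


class Node:
    __slots__ = ("label", "children", "length")

    def __init__(
        self,
        label: Optional[str] = None,
        children: tuple["Node", ...] | list["Node"] = (),
        length: Optional[float] = None,
    ):
        self.label = label
        self.children = list(children)
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.walk() if n.is_leaf)

    def copy(self) -> "Node":
        return Node(
            self.label, tuple(c.copy() for c in self.children), self.length
        )


@dataclass
class Tree:
    """A binary tree over uniquely labelled leaves.

    ``root`` has degree 3 for the unrooted representation and degree 2 when
    the tree has been rooted (e.g. on an outgroup leaf).
    """

    root: Node

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    # ------------------------------------------------------------------ I/O

    def to_newick(self, lengths: bool = True) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.label:
                    body += node.label
            if lengths and node.length is not None:
                body += f":{node.length:.6g}"
            return body

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                return Node(label=label, length=dnode.edge.length)
            return Node(
                children=tuple(convert(c) for c in dnode.child_nodes()),
                length=dnode.edge.length,
            )

        return cls(convert(dt.seed_node))

    # ------------------------------------------------------------- topology

    def _find_leaf(self, label: str) -> Node:
        for node in self.root.walk():
            if node.is_leaf and node.label == label:
                return node
        raise LabelLookupError(f"leaf {label!r} not in tree")

    def _parent_map(self) -> dict[int, Optional[Node]]:
        parent: dict[int, Optional[Node]] = {id(self.root): None}
        for node in self.root.walk():
            for child in node.children:
                parent[id(child)] = node
        return parent

    def root_on(self, outgroup: str) -> "Tree":
        """Return a rooted copy with ``outgroup`` as one child of the root.

        The root's other child carries the whole remaining (ingroup)
        topology. Degree-2 nodes created by removing a previous rooting are
        suppressed, with their edge lengths summed.
        """
        leaf = self._find_leaf(outgroup)
        parent = self._parent_map()
        anchor = parent[id(leaf)]
        if anchor is None:
            raise InputError("cannot root a single-leaf tree")

        def hang(node: Node, avoid: Node) -> Node:
            """Rebuild the subtree at ``node`` growing away from ``avoid``."""
            kids: list[Node] = []
            for c in node.children:
                if c is avoid:
                    continue
                sub = hang(c, node)
                sub.length = c.length
                kids.append(sub)
            p = parent[id(node)]
            if p is not None and p is not avoid:
                sub = hang(p, node)
                sub.length = node.length  # edge node<->p, now traversed upward
                kids.append(sub)
            return Node(node.label if node.is_leaf else None, tuple(kids))

        rest = _suppress_unary(hang(anchor, leaf))
        rest.length = 0.0
        out = Node(leaf.label, length=leaf.length)
        return Tree(Node(children=(out, rest)))

    def unrooted(self) -> "Tree":
        """Return an unrooted view (degree-3 root), merging a degree-2 root."""
        if not self.is_rooted:
            return self.copy()
        a, b = self.root.children
        if a.is_leaf and b.is_leaf:
            raise InputError("a two-leaf tree has no unrooted binary form")
        if a.is_leaf:  # keep the internal side as the new root
            a, b = b, a
        new_root = a.copy()
        hung = b.copy()
        hung.length = (a.length or 0.0) + (b.length or 0.0)
        new_root.children.append(hung)
        new_root.length = None
        return Tree(new_root)

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Internal-edge splits of the unrooted topology.

        Each split is canonicalized as the side *not* containing the
        lexicographically smallest leaf label, so two trees share a split
        iff they share the corresponding interior branch.
        """
        tree = self.unrooted() if self.is_rooted else self
        all_leaves = tree.leaf_labels()
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def collect(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset((node.label,))
            below = frozenset().union(*(collect(c) for c in node.children))
            if node is not tree.root and 2 <= len(below) <= len(all_leaves) - 2:
                splits.add(below if ref not in below else all_leaves - below)
            return below

        collect(tree.root)
        return frozenset(splits)

    def leaf_distances(self) -> tuple[tuple[str, ...], "list[list[float]]"]:
        """Patristic (path-length) distances between all leaf pairs."""
        adjacency: dict[int, list[tuple[Node, float]]] = {}
        for node in self.root.walk():
            for child in node.children:
                w = child.length or 0.0
                adjacency.setdefault(id(node), []).append((child, w))
                adjacency.setdefault(id(child), []).append((node, w))
        leaves = sorted(n.label for n in self.root.walk() if n.is_leaf)
        nodes = {n.label: n for n in self.root.walk() if n.is_leaf}
        dist = [[0.0] * len(leaves) for _ in leaves]
        for i, la in enumerate(leaves):
            # Dijkstra-free BFS: trees have unique paths
            seen = {id(nodes[la])}
            frontier = [(nodes[la], 0.0)]
            acc: dict[str, float] = {}
            while frontier:
                node, d = frontier.pop()
                if node.is_leaf and node.label != la:
                    acc[node.label] = d
                for nb, w in adjacency.get(id(node), ()):
                    if id(nb) not in seen:
                        seen.add(id(nb))
                        frontier.append((nb, d + w))
            for j, lb in enumerate(leaves):
                if lb != la:
                    dist[i][j] = acc[lb]
        return tuple(leaves), dist


def _suppress_unary(node: Node) -> Node:
    """Splice out degree-2 internal nodes, summing the two edge lengths."""
    node.children = [_suppress_unary(c) for c in node.children]
    if len(node.children) == 1 and node.label is None:
        child = node.children[0]
        if node.length is not None or child.length is not None:
            child.length = (node.length or 0.0) + (child.length or 0.0)
        return child
    return node
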