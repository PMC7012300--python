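"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own tree-building code
paths: topology enumeration is exhaustive leaf insertion, branch fitting is
ordinary least squares on the path-incidence system, and rooted-topology
identity is judged from clade sets extracted with dendropy's own parser.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from treestab import Alignment, DistanceMatrix, canonical_key
from treestab.tree import Node, Tree


# --------------------------------------------------------------- fixtures


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment.from_records([("a", "ACGT"), ("b", "ACGA")])


@pytest.fixture
def quartet_alignment() -> Alignment:
    """Two clearly separated identical pairs: (w,x) vs (y,z)."""
    left = "ACGT" * 50
    right = "TGCA" * 50
    return Alignment.from_records(
        [("w", left), ("x", left), ("y", right), ("z", right)]
    )


# ------------------------------------------------- topology enumeration


def _tree_edges(root: Node) -> list[tuple[Node, Node]]:
    return [(n, c) for n in root.walk() for c in n.children]


def enumerate_unrooted(labels: list[str]) -> list[Tree]:
    """All unrooted binary topologies over the labels, by exhaustive leaf
    insertion into every edge (1, 1, 3, 15, 105, ... trees)."""
    assert len(labels) >= 3
    roots = [
        Node(children=(Node(labels[0]), Node(labels[1]), Node(labels[2])))
    ]
    for label in labels[3:]:
        grown: list[Node] = []
        for base in roots:
            n_edges = len(_tree_edges(base))
            for k in range(n_edges):
                root = base.copy()
                parent, child = _tree_edges(root)[k]
                joint = Node(children=(child, Node(label)))
                parent.children[parent.children.index(child)] = joint
                grown.append(root)
        roots = grown
    return [Tree(r) for r in roots]


def enumerate_rooted_keys(labels: list[str]) -> set:
    """Canonical keys of all rooted binary topologies over the labels
    (realized as unrooted topologies over labels + a root handle)."""
    handle = "__root__"
    return {
        canonical_key(t, handle) for t in enumerate_unrooted(list(labels) + [handle])
    }


# ------------------------------------------------- least-squares oracle


def ls_residual(tree: Tree, dm: DistanceMatrix) -> float:
    """Ordinary-least-squares lack of fit of a topology to a distance matrix.

    Branch lengths are fit by unconstrained OLS on the leaf-pair path
    incidence system; the residual sum of squares is the score. An additive
    matrix scores (numerically) zero on its generating topology only.
    """
    edges = _tree_edges(tree.root)
    edge_index = {id(c): k for k, (_, c) in enumerate(edges)}
    parent = {id(c): p for p, c in edges}
    leaves = {n.label: n for n in tree.root.walk() if n.is_leaf}

    def path_edges(label: str) -> dict[int, bool]:
        out = {}
        node = leaves[label]
        while id(node) in parent:
            out[edge_index[id(node)]] = True
            node = parent[id(node)]
        return out

    up = {l: path_edges(l) for l in dm.labels}
    pairs = list(itertools.combinations(dm.labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        sym = set(up[a]) ^ set(up[b])
        A[r, list(sym)] = 1.0
        y[r] = dm[a, b]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


def best_ls_topology(dm: DistanceMatrix):
    """Exhaustively scored best-fit unrooted topology (canonical key)."""
    best = min(enumerate_unrooted(list(dm.labels)), key=lambda t: ls_residual(t, dm))
    return canonical_key(best)


# ------------------------------------------------------ dendropy oracle


def dendropy_clade_sets(newick: str) -> frozenset:
    """Rooted clade leaf-sets of a Newick tree, via dendropy parsing only."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    clades = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        clades.add(leaves)
    return frozenset(clades)


def additive_matrix(tree: Tree) -> DistanceMatrix:
    labels, d = tree.leaf_distances()
    return DistanceMatrix(tuple(labels), np.array(d))
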