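"""Canonical topology keys, label transport, and closest-outgroup choice.

A :class:`TopologyKey` is a canonical, hashable encoding of a leaf-labelled
(rooted) topology: children are stored sorted by their rendered form, so the
key is invariant under child-order swaps and internal-node identity. Two
trees yield equal keys iff they have identical leaf sets and identical
topology. Subtree comparison throughout this package is *rooted*: a clade
plus a designated outgroup leaf is reduced to the rooted topology of the
clade, with the outgroup used only to place the root (for a three-leaf
clade this yields the familiar three alternatives ((A,B),C), ((B,C),A),
((A,C),B)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .errors import InputError, LabelLookupError
from .distmat_nj import DistanceMatrix
from .seq_io import LabelMap
from .tree import Node, Tree


@dataclass(frozen=True)
class TopologyKey:
    """Canonical encoding of a rooted leaf-labelled topology."""

    node: Union[str, tuple["TopologyKey", ...]]

    def __post_init__(self) -> None:
        if isinstance(self.node, tuple):
            object.__setattr__(self, "node", tuple(sorted(self.node, key=str)))

    @property
    def is_leaf(self) -> bool:
        return isinstance(self.node, str)

    def __str__(self) -> str:
        if isinstance(self.node, str):
            return self.node
        return "(" + ",".join(str(k) for k in self.node) + ")"

    def __repr__(self) -> str:
        return f"TopologyKey({str(self)!r})"

    def leaves(self) -> frozenset[str]:
        if isinstance(self.node, str):
            return frozenset((self.node,))
        return frozenset().union(*(k.leaves() for k in self.node))

    def relabel(self, label_map: LabelMap) -> "TopologyKey":
        """Transport the key into another family's label universe."""
        if isinstance(self.node, str):
            return TopologyKey(label_map[self.node])
        return TopologyKey(tuple(k.relabel(label_map) for k in self.node))

    @classmethod
    def from_newick(cls, newick: str) -> "TopologyKey":
        return _key_of(Tree.from_newick(newick).root)


def _key_of(node: Node) -> TopologyKey:
    if node.is_leaf:
        return TopologyKey(node.label)
    return TopologyKey(tuple(sorted((_key_of(c) for c in node.children), key=str)))


def canonical_key(tree: Tree, outgroup: Optional[str] = None) -> TopologyKey:
    """Canonical key of a tree, rooted on ``outgroup`` when given.

    With an outgroup, the key covers the *non-outgroup* leaves only: the
    outgroup places the root and is excluded. Without one, a rooted tree
    (degree-2 root) is encoded as-is, and an unrooted tree is first rooted
    on its lexicographically smallest leaf so that equal keys mean equal
    unrooted topology.
    """
    if outgroup is not None:
        rooted = tree.root_on(outgroup)
        out_child, in_child = rooted.root.children
        if out_child.label != outgroup:  # pragma: no cover - fixed child order
            out_child, in_child = in_child, out_child
        return _key_of(in_child)
    if tree.is_rooted or tree.n_leaves == 2:
        return _key_of(tree.root)
    anchor = min(tree.leaf_labels())
    return _key_of(tree.root_on(anchor).root)


def map_labels(key: TopologyKey, label_map: LabelMap) -> TopologyKey:
    """Relabel a topology key through a family A → family B label map."""
    return key.relabel(label_map)


def closest_outgroup(dm: DistanceMatrix, ingroup: frozenset[str] | set[str]) -> str:
    """The non-ingroup label with smallest mean p-distance to the ingroup.

    Ties break on the lexicographically smaller label.
    """
    ingroup = frozenset(ingroup)
    missing = ingroup - set(dm.labels)
    if missing:
        raise LabelLookupError(
            f"ingroup label(s) not in distance matrix: {', '.join(sorted(missing))}"
        )
    in_idx = [i for i, l in enumerate(dm.labels) if l in ingroup]
    candidates = [
        (float(np.mean(dm.d[i, in_idx])), dm.labels[i])
        for i in range(len(dm.labels))
        if dm.labels[i] not in ingroup
    ]
    if not candidates:
        raise InputError("no outgroup candidate: every label is in the ingroup")
    return min(candidates)[1]


def n_rooted_topologies(n_leaves: int) -> int:
    """Number of distinct rooted binary topologies on ``n_leaves`` labelled
    leaves: the double factorial (2n-3)!! (3 for n=3, 105 for n=5)."""
    if n_leaves < 2:
        raise InputError("rooted topologies are defined for >= 2 leaves")
    count = 1
    for k in range(3, 2 * n_leaves - 2, 2):
        count *= k
    return count


@dataclass(frozen=True)
class CladeSpec:
    """A clade to analyse: >= 2 ingroup labels plus an optional fixed outgroup.

    When ``outgroup`` is ``None`` the closest outgroup (by mean p-distance
    on the full alignment) is chosen at run time.
    """

    ingroup: frozenset[str]
    outgroup: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingroup", frozenset(self.ingroup))
        if len(self.ingroup) < 2:
            raise InputError("a clade needs at least 2 ingroup labels")
        if self.outgroup is not None and self.outgroup in self.ingroup:
            raise InputError("outgroup must be disjoint from the ingroup")
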