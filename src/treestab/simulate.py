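"""Synthetic data: JC69 sequence evolution and duplicated-family fixtures.

The generator evolves DNA alignments along a tree under the Jukes–Cantor
model (equal base frequencies, equal substitution rates) and assembles
pairs of "duplicated" gene-family alignments whose topologies either agree
or differ by one nearest-neighbor interchange — the two regimes between
which the reproducibility statistic must discriminate. The default species
tree has nine leaves with one basal lineage serving as the natural
outgroup, internal branches of 0.08 substitutions/site and ~1 kb of
sequence, emulating the scale of a primate nuclear gene family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import exp
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .seq_io import Alignment, LabelMap
from .topology import canonical_key
from .tree import Node, Tree


@dataclass(frozen=True)
class SimConfig:
    """Sites, seed and optional fixed root sequence for JC69 simulation."""

    n_sites: int = 1000
    seed: int = 0
    root_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InputError("n_sites must be >= 1")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def evolve_jc69(tree: Tree, config: SimConfig) -> Alignment:
    """Evolve one sequence per leaf along a rooted tree under JC69.

    Each site evolves independently; on a branch of length ``t`` the
    probability that a site ends in a different base is
    ``3/4 * (1 - exp(-4t/3))``, uniform over the three alternatives.
    Branch lengths must be non-negative expected substitutions/site.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    if config.root_sequence is not None:
        from .seq_io import _encode_sequence

        root_seq = _encode_sequence("<root>", config.root_sequence)
        if root_seq.size != n:
            raise InputError("root_sequence length must equal n_sites")
        if root_seq.max() > 3:
            raise InputError("root_sequence must contain only A/C/G/T")
    else:
        root_seq = rng.integers(0, 4, size=n).astype(np.uint8)

    labels: list[str] = []
    rows: list[np.ndarray] = []

    def walk(node: Node, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length
            if t is None or t < 0:
                raise InputError(
                    f"branch above {child.label or 'internal node'!r} must have "
                    "a non-negative length"
                )
            p_change = 0.75 * (1.0 - exp(-4.0 * t / 3.0))
            mutated = rng.random(n) < p_change
            new = seq.copy()
            k = int(mutated.sum())
            if k:
                new[mutated] = (seq[mutated] + rng.integers(1, 4, size=k)) % 4
            if child.is_leaf:
                labels.append(child.label)
                rows.append(new)
            else:
                walk(child, new)

    walk(tree.root, root_seq)
    return Alignment(tuple(labels), np.vstack(rows).astype(np.uint8))


def tree_edges(tree: Tree) -> list[tuple[Node, Node]]:
    """All (parent, child) edges in deterministic preorder.

    Edge positions are stable under an NNI (nodes are exchanged in place),
    which is what makes applying the same interchange twice an involution.
    """
    return [(n, c) for n in tree.root.walk() for c in n.children]


def internal_edges(tree: Tree) -> list[int]:
    """Indices into :func:`tree_edges` whose child end is an internal node."""
    return [i for i, (_, c) in enumerate(tree_edges(tree)) if not c.is_leaf]


def nni_perturb(
    tree: Tree,
    internal_edge: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    swap: Optional[int] = None,
) -> Tree:
    """One nearest-neighbor interchange around an internal edge.

    ``internal_edge`` indexes :func:`tree_edges` of the tree (chosen at
    random among internal edges when omitted); a leaf edge is rejected.
    ``swap`` picks which child of the edge's lower node trades places with
    the sibling subtree (positions keep their branch lengths). Applying
    the same (edge, swap) pair twice restores the original topology.
    """
    new = tree.copy()
    edges = tree_edges(new)
    candidates = internal_edges(new)
    if not candidates:
        raise InputError("tree has no internal edge to rearrange")
    if internal_edge is None:
        if rng is None:
            raise InputError("need an edge index or an rng to choose one")
        internal_edge = candidates[int(rng.integers(0, len(candidates)))]
    if not 0 <= internal_edge < len(edges):
        raise InputError(
            f"edge index {internal_edge} out of range 0..{len(edges)-1}"
        )
    parent, child = edges[internal_edge]
    if child.is_leaf:
        raise InputError("cannot apply an NNI across a leaf edge")
    siblings = [c for c in parent.children if c is not child]
    if not siblings:
        raise InputError("edge has no sibling subtree to exchange")
    if swap is None:
        swap = int(rng.integers(0, len(child.children))) if rng is not None else 0
    sib = siblings[0]
    grand = child.children[swap % len(child.children)]
    # exchange subtrees; branch lengths stay with their positions
    pi = parent.children.index(sib)
    ci = child.children.index(grand)
    sib_len, grand_len = sib.length, grand.length
    parent.children[pi] = grand
    grand.length = sib_len
    child.children[ci] = sib
    sib.length = grand_len
    return new


def random_tree(
    labels: Sequence[str],
    rng: np.random.Generator,
    branch_length: tuple[float, float] = (0.02, 0.1),
) -> Tree:
    """A uniformly grown random rooted binary tree with uniform branch
    lengths, for property tests and additive-matrix oracles."""
    if len(labels) < 2:
        raise InputError("need >= 2 labels")

    def bl() -> float:
        lo, hi = branch_length
        return float(rng.uniform(lo, hi))

    root = Node(children=(Node(labels[0], length=bl()), Node(labels[1], length=bl())))
    for label in labels[2:]:
        edges = []
        for node in root.walk():
            for child in node.children:
                edges.append((node, child))
        parent, child = edges[int(rng.integers(0, len(edges)))]
        split = Node(children=(child, Node(label, length=bl())), length=child.length / 2)
        child.length = child.length / 2
        parent.children[parent.children.index(child)] = split
    return Tree(root)


def default_species_tree() -> Tree:
    """Nine-species tree with a basal outgroup lineage (``sp9``).

    Internal branches are 0.08 substitutions/site and terminals 0.05–0.12,
    giving p-distances of roughly 0.1–0.35 at 1 kb — clean but realistic
    signal for a nuclear protein-coding gene family.
    """
    newick = (
        "((((sp1:0.05,sp2:0.06):0.08,sp3:0.07):0.08,"
        "(sp4:0.06,(sp5:0.05,sp6:0.07):0.08):0.08):0.08,"
        "(sp7:0.09,sp8:0.10):0.08,sp9:0.30);"
    )
    return Tree.from_newick(newick)


def make_family_pair(
    species_tree: Tree,
    agree: bool,
    config: SimConfig,
    outgroup: Optional[str] = None,
) -> tuple[Alignment, Alignment, LabelMap]:
    """Two duplicated-family alignments plus their species label map.

    Family A evolves on ``species_tree``; family B on the same tree
    (``agree=True``) or on a copy perturbed by one NNI that is guaranteed
    to change the compared topology (rooted on ``outgroup`` when given,
    unrooted otherwise). Labels are prefixed ``A_``/``B_`` and paired by
    species in the returned map.
    """
    if species_tree.n_leaves < 4:
        raise InputError("species tree needs >= 4 leaves")
    seed_a, seed_b, seed_nni = _spawn_seeds(config.seed, 3)

    tree_b = species_tree
    if not agree:
        rng = np.random.default_rng(seed_nni)
        reference = canonical_key(species_tree, outgroup)
        for _ in range(100):
            candidate = nni_perturb(species_tree, rng=rng)
            if canonical_key(candidate, outgroup) != reference:
                tree_b = candidate
                break
        else:  # pragma: no cover - cannot happen on binary trees with >=4 leaves
            raise InputError("no NNI changes the compared topology")

    aln_a = _relabel(evolve_jc69(species_tree, replace(config, seed=seed_a)), "A_")
    aln_b = _relabel(evolve_jc69(tree_b, replace(config, seed=seed_b)), "B_")
    label_map = LabelMap(
        {f"A_{sp}": f"B_{sp}" for sp in sorted(species_tree.leaf_labels())}
    )
    return aln_a, aln_b, label_map


def _relabel(alignment: Alignment, prefix: str) -> Alignment:
    return Alignment(tuple(prefix + l for l in alignment.labels), alignment.data)
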