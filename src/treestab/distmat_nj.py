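"""p-distance matrices and neighbor joining on them (the "NJp" method).

The p-distance between two aligned sequences is the fraction of compared
sites at which they differ. Sites containing a gap or ``N`` are removed
either for the whole matrix (complete deletion, the default) or per pair
(pairwise deletion). Trees are built with the Saitou–Nei neighbor-joining
algorithm; the Q-criterion pair choice breaks ties on the lexicographically
smallest pair of cluster labels so the topology is a pure function of the
distance values, independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import DataError, InputError
from .seq_io import MISSING_CODE, Alignment
from .tree import Node, Tree

DeletionMode = Literal["complete", "pairwise"]


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """A symmetric matrix of p-distances over ordered labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or self.d.min() < 0 or self.d.max() > 1:
            raise InputError("p-distances must be finite and within [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def to_phylip(self, path: str | Path) -> None:
        """Write a square PHYLIP-style distance matrix (tab separated)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def p_distance_matrix(
    alignment: Alignment, deletion_mode: DeletionMode = "complete"
) -> DistanceMatrix:
    """Proportion-of-differences matrix with gap/N handling.

    ``complete``: drop every column containing a gap or ``N`` anywhere, then
    compare. ``pairwise``: for each pair, compare only the columns where
    both sequences have a determined base.
    """
    data = alignment.data
    n = alignment.n_seqs
    valid = data < MISSING_CODE  # A/C/G/T only
    d = np.zeros((n, n))
    if deletion_mode == "complete":
        keep = valid.all(axis=0)
        if not keep.any():
            raise DataError(
                "no sites free of gaps/N under complete deletion for pair "
                f"({alignment.labels[0]!r}, {alignment.labels[1]!r}) "
                "(and all other pairs)"
            )
        x = data[:, keep]
        diff = x[:, None, :] != x[None, :, :]
        d = diff.mean(axis=2)
    elif deletion_mode == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                m = int(both.sum())
                if m == 0:
                    raise DataError(
                        "zero comparable sites for pair "
                        f"({alignment.labels[i]!r}, {alignment.labels[j]!r})"
                    )
                d[i, j] = d[j, i] = np.count_nonzero(
                    data[i, both] != data[j, both]
                ) / m
    else:
        raise InputError(f"unknown deletion mode {deletion_mode!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(alignment.labels, d)


def _clamp(x: float) -> float:
    return x if x > 0.0 else 0.0


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a distance matrix.

    The matrix is processed in sorted-label order and Q-matrix ties pick
    the lexicographically smallest cluster-label pair, so the output
    topology is invariant to the order of the input labels. Negative
    branch-length estimates are clamped to zero after the topology is
    fixed. The returned tree is unrooted (degree-3 root).
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError(f"neighbor joining needs >= 3 labels, got {n}")

    order = sorted(range(n), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    D = dm.d[np.ix_(order, order)].astype(float).copy()
    nodes: list[Node] = [Node(label=l) for l in labels]
    # smallest leaf label within each active cluster, for canonical ties
    min_label: list[str] = list(labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        i, j = min(
            ((int(a), int(b)) for a, b in cand if a < b),
            key=lambda ij: tuple(sorted((min_label[ij[0]], min_label[ij[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        joined = Node(
            children=(
                _with_length(nodes[i], _clamp(li)),
                _with_length(nodes[j], _clamp(lj)),
            )
        )
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [joined]
        min_label = [min_label[k] for k in keep] + [
            min(min_label[i], min_label[j])
        ]

    # final 3-point formulas
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = Node(
        children=(
            _with_length(a, _clamp(0.5 * (dab + dac - dbc))),
            _with_length(b, _clamp(0.5 * (dab + dbc - dac))),
            _with_length(c, _clamp(0.5 * (dac + dbc - dab))),
        )
    )
    return Tree(root)


def _with_length(node: Node, length: float) -> Node:
    node.length = length
    return node


def build_tree(
    alignment: Alignment, deletion_mode: DeletionMode = "complete"
) -> tuple[Tree, DistanceMatrix]:
    """Convenience: p-distance matrix and its NJ tree in one call."""
    dm = p_distance_matrix(alignment, deletion_mode)
    return nj_tree(dm), dm
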