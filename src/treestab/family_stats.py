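"""Stability (Ps) and reproducibility (Pr) of inferred subtree topologies.

Ps of a clade is the bootstrap frequency of its modal rooted topology: how
stable the inferred subtree is under column resampling, independent of
which topology it is. Pr compares two homologous (typically duplicated)
gene families: Pr1 is the bootstrap frequency with which family A's clade
recovers family B's point-estimate topology (transported through a
paralog label map and rooted on each family's closest outgroup), Pr2 the
converse, and Pr their average. Identical, strongly supported topologies
give Pr near 100; families whose topologies differ give Pr near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from .bootstrap import (
    BootstrapConfig,
    FrequencyTable,
    reduced_alignment,
    resolve_outgroup,
    topology_frequencies,
)
from .distmat_nj import nj_tree, p_distance_matrix
from .errors import InputError, StabilityUndefinedError
from .seq_io import Alignment, LabelMap, build_species_map
from .topology import CladeSpec, TopologyKey, canonical_key
from .tree import Node

TopologySource = Literal["subtree", "full-tree"]


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding (so 0.25 → 0.3 at one digit)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StabilityResult:
    """Ps of one clade, with the full topology-frequency table behind it."""

    ps: float
    modal_key: TopologyKey
    freq: FrequencyTable
    outgroup: str
    n_replicates: int
    seed: int


@dataclass(frozen=True)
class ReproducibilityResult:
    """Pr1/Pr2/Pr between two clades, with the topologies compared."""

    pr1: float
    pr2: float
    pr: float
    t1: TopologyKey
    t2: TopologyKey
    outgroup_a: str
    outgroup_b: str
    n_replicates: int
    seed: int


def stability_from_frequencies(freq: FrequencyTable) -> tuple[float, TopologyKey]:
    """Ps and modal topology from a replicate tally.

    Ps is the maximum percentage in the table; modal ties resolve to the
    smallest canonical key rendering.
    """
    if not freq.counts:
        raise InputError("empty frequency table")
    key, ps = freq.modal()
    return ps, key


def compute_ps(
    alignment: Alignment, clade: CladeSpec, config: BootstrapConfig
) -> StabilityResult:
    """Stability of a clade: bootstrap frequency of its modal rooted topology."""
    if len(clade.ingroup) < 3:
        raise StabilityUndefinedError(
            "Ps is undefined for clades of fewer than 3 sequences"
        )
    freq = topology_frequencies(alignment, clade, config)
    ps, modal = stability_from_frequencies(freq)
    return StabilityResult(
        ps=ps,
        modal_key=modal,
        freq=freq,
        outgroup=freq.outgroup,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )


def pr1_from_frequencies(freq: FrequencyTable, target: TopologyKey) -> float:
    """Frequency (percent) of one target topology in a replicate tally."""
    observed = next(iter(freq.counts))
    if target.leaves() != observed.leaves():
        raise InputError(
            "target topology's leaf set does not match the tallied clade"
        )
    return freq.percent(target)


def compute_pr1(
    alignment: Alignment,
    clade: CladeSpec,
    target: TopologyKey,
    config: BootstrapConfig,
) -> float:
    """Bootstrap frequency (percent) with which a clade recovers ``target``.

    ``target`` must be a rooted topology over exactly the clade's ingroup
    labels; 0 is returned when it never occurs among the replicates.
    """
    if target.leaves() != clade.ingroup:
        raise InputError(
            "target topology's leaf set does not equal the clade ingroup"
        )
    freq = topology_frequencies(alignment, clade, config)
    return freq.percent(target)


def point_estimate_key(
    alignment: Alignment,
    clade: CladeSpec,
    config: BootstrapConfig,
    topology_source: TopologySource = "subtree",
) -> tuple[TopologyKey, str]:
    """The clade's point-estimate rooted topology and the outgroup used.

    ``subtree``: build the NJ tree from the reduced alignment (ingroup plus
    outgroup) — the same data universe the bootstrap resamples. ``full-tree``:
    build the NJ tree from the whole alignment and read the clade's rooted
    topology off it; the clade must be monophyletic there.
    """
    outgroup = resolve_outgroup(alignment, clade, config.deletion_mode)
    if topology_source == "subtree":
        sub = reduced_alignment(alignment, clade, outgroup)
        tree = nj_tree(p_distance_matrix(sub, config.deletion_mode))
        return canonical_key(tree, outgroup), outgroup
    if topology_source == "full-tree":
        tree = nj_tree(p_distance_matrix(alignment, config.deletion_mode))
        rooted = tree.root_on(outgroup)
        node = _find_clade_node(rooted.root, clade.ingroup)
        if node is None:
            raise InputError(
                "clade is not monophyletic in the full-alignment tree; "
                "use topology_source='subtree'"
            )
        return _subtree_key(node), outgroup
    raise InputError(f"unknown topology source {topology_source!r}")


def _find_clade_node(root: Node, ingroup: frozenset[str]) -> Optional[Node]:
    for node in root.walk():
        if node.leaf_labels() == ingroup:
            return node
    return None


def _subtree_key(node: Node) -> TopologyKey:
    if node.is_leaf:
        return TopologyKey(node.label)
    return TopologyKey(tuple(sorted((_subtree_key(c) for c in node.children), key=str)))


def compute_pr(
    alignment_a: Alignment,
    clade_a: CladeSpec,
    alignment_b: Alignment,
    clade_b: CladeSpec,
    label_map: LabelMap,
    config: BootstrapConfig,
    topology_source: TopologySource = "subtree",
    t1: Optional[TopologyKey] = None,
    t2: Optional[TopologyKey] = None,
) -> ReproducibilityResult:
    """Reproducibility between two homologous clades.

    ``label_map`` must map clade A's ingroup bijectively onto clade B's.
    ``t1``/``t2`` override the point-estimate topologies (e.g. read from
    user-supplied Newick trees); otherwise they come from
    :func:`point_estimate_key` under ``topology_source``. Both families may
    live in the same alignment object.
    """
    if len(clade_a.ingroup) < 3 or len(clade_b.ingroup) < 3:
        raise StabilityUndefinedError("Pr needs >= 3 sequences in each clade")
    mapped = {label_map[a] for a in clade_a.ingroup}
    if mapped != clade_b.ingroup:
        raise InputError(
            "label map does not carry clade A's ingroup onto clade B's ingroup"
        )

    if t1 is None:
        t1, outgroup_a = point_estimate_key(
            alignment_a, clade_a, config, topology_source
        )
    else:
        outgroup_a = resolve_outgroup(alignment_a, clade_a, config.deletion_mode)
    if t2 is None:
        t2, outgroup_b = point_estimate_key(
            alignment_b, clade_b, config, topology_source
        )
    else:
        outgroup_b = resolve_outgroup(alignment_b, clade_b, config.deletion_mode)
    if t1.leaves() != clade_a.ingroup or t2.leaves() != clade_b.ingroup:
        raise InputError("point-estimate topology does not cover the clade ingroup")

    freq_a = topology_frequencies(alignment_a, clade_a, config)
    freq_b = topology_frequencies(alignment_b, clade_b, config)
    pr1 = pr1_from_frequencies(freq_a, t2.relabel(label_map.inverse()))
    pr2 = pr1_from_frequencies(freq_b, t1.relabel(label_map))
    return ReproducibilityResult(
        pr1=pr1,
        pr2=pr2,
        pr=(pr1 + pr2) / 2.0,
        t1=t1,
        t2=t2,
        outgroup_a=outgroup_a,
        outgroup_b=outgroup_b,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )


def pairwise_pr(
    families: Mapping[str, tuple[Alignment, CladeSpec]],
    config: BootstrapConfig,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    label_maps: Optional[Mapping[tuple[str, str], LabelMap]] = None,
    topology_source: TopologySource = "subtree",
    map_delimiter: str = "_",
) -> pd.DataFrame:
    """Pr1/Pr2/Pr for every requested ordered family pair.

    Without explicit ``label_maps``, paralogs are paired by species token
    (the last ``map_delimiter``-separated field of each label). Percentages
    are reported rounded half-up to one decimal.
    """
    if len(families) < 2 and pairs is None:
        raise InputError("pairwise Pr needs at least 2 families")
    if pairs is None:
        pairs = list(combinations(sorted(families), 2))
    rows = []
    for name_a, name_b in pairs:
        aln_a, clade_a = families[name_a]
        aln_b, clade_b = families[name_b]
        if label_maps is not None and (name_a, name_b) in label_maps:
            lm = label_maps[(name_a, name_b)]
        else:
            lm = build_species_map(
                sorted(clade_a.ingroup), sorted(clade_b.ingroup), map_delimiter
            )
        res = compute_pr(
            aln_a, clade_a, aln_b, clade_b, lm, config, topology_source
        )
        rows.append(
            {
                "pair": f"{name_a}-{name_b}",
                "pr1": round_half_up(res.pr1),
                "pr2": round_half_up(res.pr2),
                "pr": round_half_up(res.pr),
            }
        )
    return pd.DataFrame(rows, columns=["pair", "pr1", "pr2", "pr"])
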