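"""Site-resampling bootstrap: branch support (Pb) and subtree topology
frequency tables.

Bootstrap replicates resample alignment columns with replacement (the same
column indices applied to every sequence), rebuild the NJ tree on
p-distances, and tally either interior-branch bipartitions (for Pb) or the
rooted topology of a designated clade (the shared primitive under the
stability and reproducibility statistics). Replicates are driven by
per-replicate generators spawned from one master seed, so every stochastic
output is exactly reproducible and the replicate stream for a given
(alignment, clade, config) is a pure function of the seed — the stability
and reproducibility of the same clade therefore share identical replicates
when computed with the same configuration.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .distmat_nj import DeletionMode, nj_tree, p_distance_matrix
from .errors import InputError, StabilityUndefinedError
from .seq_io import Alignment, subset
from .topology import CladeSpec, TopologyKey, canonical_key, closest_outgroup
from .tree import Tree


@dataclass(frozen=True)
class BootstrapConfig:
    """Replication count, seed and distance options for all bootstrap runs."""

    seed: int
    n_replicates: int = 1000
    deletion_mode: DeletionMode = "complete"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        if self.seed is None:
            raise InputError("an explicit seed is required for bootstrap runs")


def _replicate_rngs(config: BootstrapConfig):
    for child in np.random.SeedSequence(config.seed).spawn(config.n_replicates):
        yield np.random.default_rng(child)


def resample_columns(alignment: Alignment, rng: np.random.Generator) -> Alignment:
    """One bootstrap pseudo-alignment: columns drawn with replacement."""
    if alignment.n_sites < 1:
        raise InputError("cannot resample an alignment with no sites")
    idx = rng.integers(0, alignment.n_sites, size=alignment.n_sites)
    return Alignment(alignment.labels, alignment.data[:, idx])


@dataclass
class SupportTable:
    """Per-interior-branch bootstrap support (Pb) of a point-estimate tree."""

    tree: Tree
    counts: dict[frozenset[str], int]
    total: int
    seed: int
    deletion_mode: str

    def pb(self, bipartition: frozenset[str]) -> float:
        """Support in percent for one interior branch of the point tree."""
        if bipartition not in self.counts:
            raise InputError("bipartition is not an interior branch of the tree")
        return 100.0 * self.counts[bipartition] / self.total

    def items(self):
        return self.counts.items()

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# seed={self.seed}\treplicates={self.total}")
        buf.write(f"\tdeletion={self.deletion_mode}\n")
        buf.write("bipartition\tcount\tpb_percent\n")
        for part in sorted(self.counts, key=lambda p: (len(p), sorted(p))):
            labels = ",".join(sorted(part))
            buf.write(f"{labels}\t{self.counts[part]}\t{self.pb(part):.1f}\n")
        return buf.getvalue()


@dataclass
class FrequencyTable:
    """Bootstrap frequencies of the rooted topologies of one clade.

    Counts are integers over ``total`` replicates; percentages are derived,
    so they sum to exactly 100 up to float division of exact counts.
    """

    counts: dict[TopologyKey, int]
    total: int
    outgroup: str
    seed: int
    deletion_mode: str = "complete"

    def percent(self, key: TopologyKey) -> float:
        return 100.0 * self.counts.get(key, 0) / self.total

    def percents(self) -> dict[TopologyKey, float]:
        return {k: self.percent(k) for k in self.counts}

    def modal(self) -> tuple[TopologyKey, float]:
        """Most frequent key; count ties resolve to the smallest canonical
        rendering."""
        key = min(self.counts, key=lambda k: (-self.counts[k], str(k)))
        return key, self.percent(key)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# seed={self.seed}\treplicates={self.total}")
        buf.write(f"\toutgroup={self.outgroup}\tdeletion={self.deletion_mode}\n")
        buf.write("topology\tcount\tpercent\n")
        for key in sorted(self.counts, key=lambda k: (-self.counts[k], str(k))):
            buf.write(f"{key}\t{self.counts[key]}\t{self.percent(key):.1f}\n")
        return buf.getvalue()


def compute_pb(
    alignment: Alignment, config: BootstrapConfig
) -> tuple[Tree, SupportTable]:
    """Point-estimate NJp tree plus bootstrap support for each interior branch.

    Pb of a branch is the percentage of replicate trees containing the same
    leaf bipartition.
    """
    if alignment.n_seqs < 4:
        raise InputError("branch support needs >= 4 sequences (no interior branch)")
    point = nj_tree(p_distance_matrix(alignment, config.deletion_mode))
    target = point.bipartitions()
    counts: dict[frozenset[str], int] = {part: 0 for part in target}
    for rng in _replicate_rngs(config):
        rep = resample_columns(alignment, rng)
        rep_tree = nj_tree(p_distance_matrix(rep, config.deletion_mode))
        for part in rep_tree.bipartitions():
            if part in counts:
                counts[part] += 1
    table = SupportTable(
        tree=point,
        counts=counts,
        total=config.n_replicates,
        seed=config.seed,
        deletion_mode=config.deletion_mode,
    )
    return point, table


def resolve_outgroup(alignment: Alignment, clade: CladeSpec,
                     deletion_mode: DeletionMode = "complete") -> str:
    """The clade's outgroup: as given, else the closest by mean p-distance
    computed on the *full* alignment."""
    missing = clade.ingroup - set(alignment.labels)
    if missing:
        raise InputError(
            f"ingroup label(s) not in alignment: {', '.join(sorted(missing))}"
        )
    if clade.outgroup is not None:
        if clade.outgroup not in alignment.labels:
            raise InputError(f"outgroup {clade.outgroup!r} not in alignment")
        return clade.outgroup
    dm = p_distance_matrix(alignment, deletion_mode)
    return closest_outgroup(dm, clade.ingroup)


def reduced_alignment(alignment: Alignment, clade: CladeSpec, outgroup: str) -> Alignment:
    """Sub-alignment of the ingroup (in alignment order) plus the outgroup."""
    ordered = [l for l in alignment.labels if l in clade.ingroup]
    return subset(alignment, ordered + [outgroup])


def topology_frequencies(
    alignment: Alignment, clade: CladeSpec, config: BootstrapConfig
) -> FrequencyTable:
    """Bootstrap frequency of every rooted ingroup topology.

    The *reduced* alignment (ingroup plus one outgroup) is resampled; each
    replicate's NJ tree is rooted on the outgroup and the canonical key of
    the ingroup topology is tallied. Every replicate contributes exactly
    one key, so frequencies sum to 100%.
    """
    if len(clade.ingroup) < 3:
        raise StabilityUndefinedError(
            "subtree topology frequencies need an ingroup of >= 3 sequences"
        )
    outgroup = resolve_outgroup(alignment, clade, config.deletion_mode)
    sub = reduced_alignment(alignment, clade, outgroup)
    counts: Counter[TopologyKey] = Counter()
    for rng in _replicate_rngs(config):
        rep = resample_columns(sub, rng)
        rep_tree = nj_tree(p_distance_matrix(rep, config.deletion_mode))
        counts[canonical_key(rep_tree, outgroup)] += 1
    return FrequencyTable(
        counts=dict(counts),
        total=config.n_replicates,
        outgroup=outgroup,
        seed=config.seed,
        deletion_mode=config.deletion_mode,
    )
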