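# Methods

## Statistics

All three statistics are nonparametric bootstrap frequencies over trees
built by neighbor joining (Saitou–Nei) on p-distance matrices ("NJp").
A bootstrap replicate draws `n_sites` column indices with replacement and
applies them to every sequence, preserving within-column covariation.

**Pb (branch support).** The point-estimate tree is built from the full
alignment. Each interior branch defines a leaf bipartition (canonicalized
as the side not containing the lexicographically smallest leaf). Pb of a
branch is the percentage of replicate trees whose bipartition set contains
it. Supports are mapped onto the single point-estimate tree, not a
consensus tree.

**Ps (stability).** A clade is analysed together with exactly one outgroup
sequence: the *reduced* alignment (ingroup + outgroup) is what gets
resampled, not the full alignment. Each replicate's NJ tree is rooted on
the outgroup; the rooted topology of the ingroup (outgroup excluded) is
encoded canonically and tallied. Ps is the modal topology's percentage.
Rooted comparison is essential: an unrooted three-leaf tree has a single
topology, while the rooted problem has the three informative alternatives
a three-gene subtree can take. Ps is undefined for two-leaf clades (one
possible rooted topology; the modal frequency is vacuously 100) and the
package refuses to compute it.

**Pr (reproducibility).** For two homologous clades A and B whose members
correspond one-to-one under a label map, let T1 and T2 be the families'
point-estimate rooted topologies. Pr1 is the percentage of family A's
replicate topologies equal to T2 transported into A's label universe; Pr2
is the converse; Pr = (Pr1 + Pr2)/2, exact on integer replicate counts.
Only whole-topology identity counts — there is deliberately no partial
(per-branch) credit, so Pr drops sharply with any topological difference.
Because Ps and Pr1 for the same clade and configuration consume the same
seeded replicate stream, Pr1 ≤ Ps always holds within one configuration.

## Key procedural choices

- **Outgroup.** By default the sequence outside the ingroup with the
  smallest mean p-distance to ingroup members, computed on the full
  alignment; ties break lexicographically. It is fixed once before
  resampling (not re-chosen per replicate) and can be overridden per
  clade. Each family of a Pr comparison chooses its outgroup
  independently.
- **T1/T2 source.** Default `subtree`: the point-estimate topologies come
  from NJ on the reduced alignments — the same data universe the bootstrap
  resamples. Alternative `full-tree` reads the clade's rooted topology off
  the full-alignment NJ tree (requiring the clade to be monophyletic
  there), and `newick-file` accepts externally supplied topologies. On
  clean data the sources agree; they are all exposed because with unstable
  clades the point estimate itself is uncertain and the choice is a real
  degree of freedom.
- **Distances.** p-distance (proportion of differing compared sites).
  Gaps and `N` are missing data; default *complete deletion* (drop any
  column containing missing data anywhere) for determinism across
  replicates of the same column set; *pairwise deletion* is available.
  A pair left with zero comparable sites is an error naming the pair.
- **Neighbor joining.** Standard Q-criterion agglomeration. Labels are
  processed in sorted order and Q-ties pick the lexicographically
  smallest pair of cluster minimum-labels, making the topology a pure
  function of the distance values — invariant to input row order, and
  well-defined even when resampling makes sequences identical (no
  replicate is ever discarded, keeping frequency normalization exact).
  Negative branch-length estimates are clamped to zero after the topology
  is fixed; they are never redistributed.
- **Canonical topology keys.** A rooted topology is encoded by sorting
  children recursively by their rendered form: equal keys ⇔ identical leaf
  set and rooted topology (equivalently, rooted Robinson–Foulds distance
  zero — property-tested against dendropy's independent parse). Unrooted
  trees are keyed by rooting on their smallest leaf.
- **Randomness.** One master seed per run; per-replicate generators are
  spawned from it (`numpy` `SeedSequence`), so outputs are bit-identical
  across runs and platforms, and replicate k does not depend on how many
  replicates precede it. Seeds are recorded in every table and manifest.
- **Rounding.** Reported percentages round half-up to one decimal place;
  internal arithmetic keeps exact counts.

## Synthetic data generator

The generator exists so every statistic is testable without external
data. It evolves i.i.d. sites along a tree under JC69 (uniform base
frequencies, equal rates; per-branch change probability
`3/4·(1−e^(−4t/3))`) and builds duplicated-family pairs: family A on the
species tree, family B on the same tree (`agree=True`) or on a copy
perturbed by one nearest-neighbor interchange chosen, under the run's
seed, so that the compared (outgroup-rooted) topology actually changes —
an NNI adjacent to the root can otherwise alter the tree without altering
the rooted ingroup topology, which would make the "different topology"
regime vacuous.

Default conditions: a nine-species tree with one basal lineage as the
natural outgroup, internal branches 0.08 substitutions/site, terminals
0.05–0.12, outgroup branch 0.30, and 1,000-site alignments — the scale of
a primate nuclear gene family (nine taxa, ~930 bp) with clean but not
saturated signal (p-distances roughly 0.1–0.35). The end-to-end tests
additionally assemble 27-sequence datasets (three 9-species family clades
on a deep spine; 939 and 927 sites) to exercise the full pipeline at the
shape of a real three-region paralog dataset.

What the generator does *not* emulate: rate heterogeneity across sites,
base-composition bias, indels/alignment error, gene conversion between
paralogs, and within-clade gene duplication or loss. Passing tests
therefore demonstrate correctness of the statistics as defined and their
discriminating power under idealized signal; on real data, model
violations can lower both Ps and Pr for reasons other than topology
history.

## Degenerate inputs and tie-breaking summary

| Situation | Behaviour |
| --- | --- |
| Q-matrix tie in NJ | lexicographically smallest (min-label, min-label) pair |
| Modal-topology count tie | smallest canonical key string |
| Closest-outgroup tie | lexicographically smaller label |
| Two-leaf clade | `StabilityUndefinedError` |
| Clade not monophyletic under `full-tree` source | error suggesting `subtree` |
| Zero comparable sites for a pair | `DataError` naming the pair |
| Negative NJ branch estimate | clamped to 0, topology unaffected |

## Problem sizes used in the shipped analyses

Unit and property tests run at 3–10 taxa with 200–2,000 sites and 30–1,000
replicates; end-to-end checks use 1,000 replicates at 9–27 taxa, 20
simulated family pairs per regime for the recovery medians, and the
acceptance script mirrors those conditions. These sizes were chosen to
match the target data scale while keeping every analysis comfortably
desk-scale.

## Known limitations

- p-distance only; no model-corrected distances for tree building.
- Whole-topology matching makes Pr harsh for large clades: even one
  uncertain branch can drive Pr toward 0 while most of the topology
  agrees. This is by design (it is what makes the statistic a sharp
  duplication-history probe) but should be kept in mind when clades
  exceed ~10 leaves.
- JC69-only simulation; DNA only (no protein support).
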