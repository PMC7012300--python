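"""Stability (Ps) and reproducibility (Pr1/Pr2/Pr)."""

import numpy as np
import pytest

from treestab import (
    BootstrapConfig,
    CladeSpec,
    FrequencyTable,
    InputError,
    LabelMap,
    SimConfig,
    StabilityUndefinedError,
    TopologyKey,
    Tree,
    compute_pr,
    compute_pr1,
    compute_ps,
    default_species_tree,
    evolve_jc69,
    make_family_pair,
    pairwise_pr,
    point_estimate_key,
    pr1_from_frequencies,
    stability_from_frequencies,
)
from treestab.family_stats import round_half_up

KEY_AB_C = TopologyKey.from_newick("((A,B),C);")
KEY_BC_A = TopologyKey.from_newick("((B,C),A);")
KEY_AC_B = TopologyKey.from_newick("((A,C),B);")


def tally(counts):
    return FrequencyTable(counts=counts, total=sum(counts.values()),
                          outgroup="O", seed=0)


class TestWorkedTallyArithmetic:
    """The 850/100/50 three-topology tally: Ps is the modal percentage and
    Pr1 is the percentage of the designated alternative topology."""

    def test_ps_is_modal_percentage(self):
        freq = tally({KEY_AB_C: 850, KEY_BC_A: 100, KEY_AC_B: 50})
        ps, modal = stability_from_frequencies(freq)
        assert ps == 85.0
        assert modal == KEY_AB_C

    def test_pr1_is_target_percentage(self):
        freq = tally({KEY_AB_C: 850, KEY_BC_A: 100, KEY_AC_B: 50})
        assert pr1_from_frequencies(freq, KEY_BC_A) == 10.0

    def test_unobserved_target_scores_zero(self):
        freq = tally({KEY_AB_C: 1000})
        assert pr1_from_frequencies(freq, KEY_BC_A) == 0.0

    def test_unanimous_tally_gives_hundred(self):
        ps, _ = stability_from_frequencies(tally({KEY_AB_C: 123}))
        assert ps == 100.0

    def test_modal_count_tie_resolves_to_canonical_order(self):
        freq = tally({KEY_BC_A: 500, KEY_AB_C: 500})
        _, modal = stability_from_frequencies(freq)
        assert modal == KEY_AB_C  # "((A,B),C)" < "((B,C),A)"

    def test_ps_at_least_uniform_share(self):
        freq = tally({KEY_AB_C: 334, KEY_BC_A: 333, KEY_AC_B: 333})
        ps, _ = stability_from_frequencies(freq)
        assert ps >= 100.0 / len(freq.counts)


@pytest.fixture(scope="module")
def stable_alignment():
    tree = Tree.from_newick("(((a:0.05,b:0.05):0.2,c:0.1):0.05,o:0.4);")
    return evolve_jc69(tree, SimConfig(n_sites=800, seed=31))


class TestComputePs:
    def test_strong_clade_is_stable(self, stable_alignment):
        clade = CladeSpec(ingroup=frozenset({"a", "b", "c"}), outgroup="o")
        res = compute_ps(stable_alignment, clade, BootstrapConfig(seed=1, n_replicates=300))
        assert res.ps > 99.0
        assert str(res.modal_key) == "((a,b),c)"
        assert res.ps == res.freq.modal()[1]

    def test_two_leaf_clade_undefined(self, stable_alignment):
        clade = CladeSpec(ingroup=frozenset({"a", "b"}), outgroup="o")
        with pytest.raises(StabilityUndefinedError):
            compute_ps(stable_alignment, clade, BootstrapConfig(seed=1))


class TestComputePr1:
    def test_modal_target_of_stable_clade_near_hundred(self, stable_alignment):
        clade = CladeSpec(ingroup=frozenset({"a", "b", "c"}), outgroup="o")
        target = TopologyKey.from_newick("((a,b),c);")
        pr1 = compute_pr1(stable_alignment, clade, target,
                          BootstrapConfig(seed=2, n_replicates=300))
        assert pr1 > 99.0

    def test_leaf_set_mismatch_rejected(self, stable_alignment):
        clade = CladeSpec(ingroup=frozenset({"a", "b", "c"}), outgroup="o")
        with pytest.raises(InputError):
            compute_pr1(stable_alignment, clade, KEY_AB_C,
                        BootstrapConfig(seed=2, n_replicates=10))


@pytest.fixture(scope="module")
def agreeing_pair():
    return make_family_pair(default_species_tree(), agree=True,
                            config=SimConfig(n_sites=1000, seed=101),
                            outgroup="sp9")


@pytest.fixture(scope="module")
def disagreeing_pair():
    return make_family_pair(default_species_tree(), agree=False,
                            config=SimConfig(n_sites=1000, seed=202),
                            outgroup="sp9")


CLADE_A = CladeSpec(ingroup=frozenset(f"A_sp{i}" for i in range(1, 9)),
                    outgroup="A_sp9")
CLADE_B = CladeSpec(ingroup=frozenset(f"B_sp{i}" for i in range(1, 9)),
                    outgroup="B_sp9")


class TestComputePr:
    def test_identical_topologies_reproduce(self, agreeing_pair):
        aln_a, aln_b, lm = agreeing_pair
        res = compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, lm,
                         BootstrapConfig(seed=7, n_replicates=300))
        assert res.pr > 90.0
        assert res.t1.relabel(lm) == res.t2
        assert res.pr == (res.pr1 + res.pr2) / 2.0

    def test_nni_perturbed_family_does_not_reproduce(self, disagreeing_pair):
        aln_a, aln_b, lm = disagreeing_pair
        res = compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, lm,
                         BootstrapConfig(seed=7, n_replicates=300))
        assert res.pr1 < 5.0
        assert res.pr < 10.0

    def test_pr_is_exact_mean_on_integer_counts(self, agreeing_pair):
        aln_a, aln_b, lm = agreeing_pair
        res = compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, lm,
                         BootstrapConfig(seed=3, n_replicates=7))
        # pr1 and pr2 are percentages of integer counts out of 7 replicates
        for pct in (res.pr1, res.pr2):
            assert abs(pct * 7 / 100 - round(pct * 7 / 100)) < 1e-9
        assert res.pr == (res.pr1 + res.pr2) / 2.0

    def test_pr1_bounded_by_ps_on_shared_replicates(self, agreeing_pair):
        """With the same seed, Pr1 counts one key of the same replicate
        stream whose maximum is Ps."""
        aln_a, aln_b, lm = agreeing_pair
        config = BootstrapConfig(seed=13, n_replicates=200)
        res = compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, lm, config)
        ps = compute_ps(aln_a, CLADE_A, config).ps
        assert res.pr1 <= ps

    def test_map_must_carry_ingroup_onto_ingroup(self, agreeing_pair):
        aln_a, aln_b, _ = agreeing_pair
        # bijective, but A_sp8 lands on the outgroup B_sp9 instead of B_sp8
        pairs = {f"A_sp{i}": f"B_sp{i}" for i in range(1, 8)}
        pairs["A_sp8"] = "B_sp9"
        with pytest.raises(InputError):
            compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, LabelMap(pairs),
                       BootstrapConfig(seed=1, n_replicates=5))

    def test_small_clade_undefined(self, agreeing_pair):
        aln_a, aln_b, lm = agreeing_pair
        small = CladeSpec(ingroup=frozenset({"A_sp1", "A_sp2"}))
        with pytest.raises(StabilityUndefinedError):
            compute_pr(aln_a, small, aln_b, CLADE_B, lm,
                       BootstrapConfig(seed=1, n_replicates=5))

    def test_determinism_to_all_decimals(self, agreeing_pair):
        aln_a, aln_b, lm = agreeing_pair
        config = BootstrapConfig(seed=99, n_replicates=150)
        r1 = compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, lm, config)
        r2 = compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, lm, config)
        assert (r1.pr1, r1.pr2, r1.pr) == (r2.pr1, r2.pr2, r2.pr)


class TestTopologySources:
    def test_full_tree_and_subtree_agree_on_clean_data(self, agreeing_pair):
        aln_a, _, _ = agreeing_pair
        config = BootstrapConfig(seed=5, n_replicates=10)
        k_sub, og1 = point_estimate_key(aln_a, CLADE_A, config, "subtree")
        k_full, og2 = point_estimate_key(aln_a, CLADE_A, config, "full-tree")
        assert og1 == og2 == "A_sp9"
        assert k_sub == k_full

    def test_explicit_topology_override(self, agreeing_pair):
        aln_a, aln_b, lm = agreeing_pair
        config = BootstrapConfig(seed=5, n_replicates=100)
        t1, _ = point_estimate_key(aln_a, CLADE_A, config)
        t2 = t1.relabel(lm)
        res = compute_pr(aln_a, CLADE_A, aln_b, CLADE_B, lm, config,
                         t1=t1, t2=t2)
        assert res.t1 == t1 and res.t2 == t2


class TestPairwisePr:
    def test_self_pair_under_identity_map_is_symmetric(self, agreeing_pair):
        aln_a, _, _ = agreeing_pair
        ident = LabelMap({l: l for l in CLADE_A.ingroup})
        families = {"F1": (aln_a, CLADE_A), "F2": (aln_a, CLADE_A)}
        table = pairwise_pr(families, BootstrapConfig(seed=17, n_replicates=100),
                            pairs=[("F1", "F2")],
                            label_maps={("F1", "F2"): ident})
        row = table.iloc[0]
        assert row["pr1"] == row["pr2"]

    def test_species_token_default_mapping(self, agreeing_pair):
        aln_a, aln_b, _ = agreeing_pair
        families = {"A": (aln_a, CLADE_A), "B": (aln_b, CLADE_B)}
        table = pairwise_pr(families, BootstrapConfig(seed=23, n_replicates=100))
        assert list(table.columns) == ["pair", "pr1", "pr2", "pr"]
        assert len(table) == 1
        assert table.iloc[0]["pr"] > 90.0


@pytest.mark.parametrize(
    "value, expected",
    [(0.25, 0.3), (0.749, 0.7), (12.65, 12.7), (0.04, 0.0), (99.95, 100.0)],
)
def test_percent_rounding_is_half_up(value, expected):
    assert round_half_up(value) == expected
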