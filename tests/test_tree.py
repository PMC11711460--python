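"""Containment classification, tree assembly, assignment, annotation."""

import numpy as np
import pandas as pd
import pytest

import ylandscape as yl
from ylandscape.matrix import MISSING
from ylandscape.tree import ROOT, StructuralError

from helpers import (assignment_accuracy, make_matrix, three_gamete_compatible,
                     truth_member_family)


# ---------------------------------------------------------------------------
# pairwise classification


@pytest.mark.parametrize("a,b,expected", [
    ({"s1", "s2", "s3"}, {"s1", "s2"}, "a_over_b"),
    ({"s1", "s2"}, {"s1", "s2", "s3"}, "b_over_a"),
    ({"s1", "s2"}, {"s1", "s2"}, "equivalent"),
    ({"s1", "s2"}, {"s2", "s3"}, "conflict"),
    ({"s1"}, {"s2"}, "disjoint"),
    (set(), set(), "ambiguous"),
])
def test_classify_pair(a, b, expected):
    assert yl.classify_pair(a, b) == expected


def test_classify_pair_insufficient_overlap_is_ambiguous():
    assert yl.classify_pair({"s1"}, {"s2"}, universe={"s1", "s2"},
                            min_informative=3) == "ambiguous"


# ---------------------------------------------------------------------------
# MAC filter


def test_filter_mac_boundary_and_counts():
    G = np.zeros((10, 10), dtype=np.int8)
    for i in range(10):
        G[i, : i + 1] = 1  # carrier counts 1..10
    gm = make_matrix(G)
    kept = yl.filter_mac(gm, 5)
    assert kept.n_variants == 6
    assert kept.derived_counts().min() == 5
    assert yl.filter_mac(gm, 5).n_variants == 6  # 4 carriers dropped


# ---------------------------------------------------------------------------
# tree assembly


def test_single_variant_tree():
    G = np.array([[1] * 5 + [0] * 5], dtype=np.int8)
    tree, dropped = yl.build_tree(make_matrix(G))
    assert dropped == []
    assert len(tree) == 1
    child = tree.root.children[0]
    assert tree.clades[child].members == {f"s{j}" for j in range(1, 6)}


def test_worked_nested_matrix():
    """{all}, {1-3}, {1-2} nest into a chain; {4,5} is their sibling."""
    G = np.array([
        [1, 1, 1, 1, 1, 1],   # v1: all
        [1, 1, 1, 0, 0, 0],   # v2: s1-3
        [1, 1, 0, 0, 0, 0],   # v3: s1-2
        [0, 0, 0, 1, 1, 0],   # v4: s4-5
    ], dtype=np.int8)
    tree, dropped = yl.build_tree(make_matrix(G))
    assert dropped == []
    by_members = {frozenset(c.members): name
                  for name, c in tree.clades.items()}
    n_all = by_members[frozenset({"s1", "s2", "s3", "s4", "s5", "s6"})]
    n_123 = by_members[frozenset({"s1", "s2", "s3"})]
    n_12 = by_members[frozenset({"s1", "s2"})]
    n_45 = by_members[frozenset({"s4", "s5"})]
    assert tree.clades[n_all].parent == ROOT
    assert tree.clades[n_123].parent == n_all
    assert tree.clades[n_12].parent == n_123
    assert tree.clades[n_45].parent == n_all
    tree.validate()


def test_equivalent_variants_collapse_to_one_clade():
    G = np.array([
        [1, 1, 1, 0, 0, 0],
        [1, 1, 1, 0, 0, 0],
    ], dtype=np.int8)
    tree, _ = yl.build_tree(make_matrix(G))
    assert len(tree) == 1
    assert set(tree.clades[tree.root.children[0]].markers) == {"v1", "v2"}


def test_conflict_variant_dropped_greedily():
    G = np.array([
        [1, 1, 1, 1, 0, 0],   # v1
        [1, 1, 0, 0, 0, 0],   # v2 nested in v1
        [0, 0, 1, 0, 1, 1],   # v3 conflicts with v1 (and overlaps nothing else)
    ], dtype=np.int8)
    tree, dropped = yl.build_tree(make_matrix(G))
    # v3 has fewer carriers than v1 at equal conflict count -> v3 dropped
    assert dropped == ["v3"]
    tree.validate()


def test_compatibility_oracle_on_random_matrices():
    """build_tree succeeds without drops iff the exhaustive three-gamete
    scan finds no violating pair (complete 8x8 matrices)."""
    rng = np.random.default_rng(2024)
    agree = 0
    for _ in range(60):
        G = (rng.random((8, 8)) < 0.4).astype(np.int8)
        compatible = three_gamete_compatible(G)
        _, dropped = yl.build_tree(make_matrix(G))
        agree += (len(dropped) == 0) == compatible
    assert agree == 60


def test_noiseless_reconstruction_matches_truth(noiseless_cohort, small_tree):
    gm, _ = yl.apply_qc(noiseless_cohort.gm, noiseless_cohort.mask)
    tree, dropped = yl.build_tree(yl.filter_mac(gm, 5))
    assert dropped == []
    assert tree.member_family() == truth_member_family(
        small_tree, noiseless_cohort.truth_samples, min_members=5)
    haps = yl.assign_samples(tree, gm)
    acc = assignment_accuracy(small_tree, noiseless_cohort.truth_samples,
                              tree, haps)
    assert acc == 1.0
    tree.validate()


def test_assignment_robust_to_missingness():
    """At 5% missing calls, sample assignment accuracy stays >= 99%."""
    demo = yl.DemographyConfig.default(n_samples=900, seed=31)
    sim_tree = yl.simulate_tree(demo, depth=3, branching=2)
    noise = yl.NoiseConfig(missing_rate=0.05, het_artifact_rate=0.0,
                           frac_fail_fs=0, frac_fail_mq=0, frac_fail_dp=0,
                           frac_nonpass=0, frac_mask=0, frac_low_call=0,
                           n_monomorphic=0, frac_missing_geo=0,
                           frac_foreign=0, frac_missing_father=0,
                           frac_relative=0, n_high_missing_samples=0)
    cohort = yl.simulate_cohort(sim_tree, demo, noise)
    gm = cohort.gm  # skip the call-rate filter: 5% missing is the test point
    tree, _ = yl.build_tree(yl.filter_mac(gm, 5))
    haps = yl.assign_samples(tree, gm)
    acc = assignment_accuracy(sim_tree, cohort.truth_samples, tree, haps)
    assert acc >= 0.99


def test_majority_rule_with_missing_marker():
    """A sample missing one of two equivalent defining markers but derived
    at the other is still assigned to the clade."""
    G = np.array([
        [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        [MISSING, 1, 1, 1, 1, 0, 0, 0, 0, 0],
    ], dtype=np.int8)
    gm = make_matrix(G)
    tree, _ = yl.build_tree(gm)
    haps = yl.assign_samples(tree, gm)
    clade = tree.root.children[0]
    assert haps["s1"] == clade
    assert haps["s6"] == ROOT  # ancestral at everything stays unassigned


def test_containment_invariant(noisy_cohort):
    gm, _ = yl.apply_qc(noisy_cohort.gm, noisy_cohort.mask)
    tree, _ = yl.build_tree(yl.filter_mac(gm, 5))
    for name, clade in tree.clades.items():
        for ch in clade.children:
            assert tree.clades[ch].members <= clade.members


# ---------------------------------------------------------------------------
# annotation


def _star_tree(n_clades, members_per_clade=1):
    G = np.zeros((n_clades, n_clades), dtype=np.int8)
    np.fill_diagonal(G, 1)
    gm = make_matrix(G)
    tree, _ = yl.build_tree(gm)
    return tree


def test_novelty_percentage_paper_scale():
    tree = _star_tree(363)
    markers = [tree.clades[c].markers[0] for c in tree.preorder() if c != ROOT]
    aliases = pd.DataFrame({"marker": markers[:259],
                            "label": [f"N-M{i}" for i in range(259)]})
    _, ledger = yl.annotate_clades(tree, aliases)
    assert ledger["n_clades"] == 363
    assert ledger["n_novel"] == 104
    assert ledger["pct_novel"] == 28.7


def test_all_aliased_zero_novel():
    tree = _star_tree(8)
    markers = [tree.clades[c].markers[0] for c in tree.preorder() if c != ROOT]
    aliases = pd.DataFrame({"marker": markers,
                            "label": [f"H{i}" for i in range(8)]})
    _, ledger = yl.annotate_clades(tree, aliases)
    assert ledger["pct_novel"] == 0.0


def test_three_of_eight_novel():
    tree = _star_tree(8)
    markers = [tree.clades[c].markers[0] for c in tree.preorder() if c != ROOT]
    aliases = pd.DataFrame({"marker": markers[:5],
                            "label": [f"H{i}" for i in range(5)]})
    _, ledger = yl.annotate_clades(tree, aliases)
    assert ledger["pct_novel"] == 37.5
    novel = [c for c in tree.clades.values() if c.novel]
    assert all(c.label.startswith("ROOT*") for c in novel)


def test_alias_conflict_warns_and_takes_lexicographic_first():
    G = np.array([[1, 1, 1, 0, 0], [1, 1, 1, 0, 0]], dtype=np.int8)
    tree, _ = yl.build_tree(make_matrix(G))
    aliases = pd.DataFrame({"marker": ["v1", "v2"], "label": ["Z-9", "A-1"]})
    with pytest.warns(UserWarning, match="disagree"):
        tree, _ = yl.annotate_clades(tree, aliases)
    assert tree.clades[tree.root.children[0]].label == "A-1"


def test_duplicate_alias_markers_rejected():
    tree = _star_tree(2)
    aliases = pd.DataFrame({"marker": ["v1", "v1"], "label": ["A", "B"]})
    with pytest.raises(ValueError):
        yl.annotate_clades(tree, aliases)


def test_newick_export_parses(noiseless_cohort):
    import dendropy

    gm, _ = yl.apply_qc(noiseless_cohort.gm, noiseless_cohort.mask)
    tree, _ = yl.build_tree(yl.filter_mac(gm, 5))
    nwk = tree.to_newick()
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    n_leaves = sum(1 for c in tree.clades.values()
                   if not c.children and c.name != ROOT)
    assert len(parsed.leaf_nodes()) == n_leaves
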