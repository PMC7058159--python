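"""Unrooted-tree primitives: Newick I/O, pruning, RF, placement, monophyly."""

import dendropy
import numpy as np
import pytest

from canaryseq.errors import NewickError, TreeError
from canaryseq.treeops import (
    is_monophyletic,
    parse_newick,
    placement,
    prune_leaves,
    restrict_to_shared,
    rf_distance,
    same_placement,
    write_newick,
)

from conftest import random_tree


def dendropy_rf(nwk1: str, nwk2: str) -> int:
    """Independent Robinson-Foulds oracle via dendropy."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    t1.is_rooted = t2.is_rooted = False
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestParseWrite:
    def test_four_leaf_parse(self):
        t = parse_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert t.leaf_set == {"A", "B", "C", "D"}
        assert t.splits() == frozenset({frozenset({"C", "D"})})

    @pytest.mark.parametrize("bad", ["(A,(B);", "(A,B;", "((A,B),(A,C));", "(A,B);"])
    def test_parse_errors(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_rooted_input_stored_unrooted(self):
        rooted = parse_newick("((A:1,B:1):2,(C:1,D:1):3);")
        # degree-2 root suppressed: central edge has summed length 5
        assert rooted.splits() == frozenset({frozenset({"C", "D"})})
        assert not any(
            len(nbrs) == 2 for node, nbrs in rooted.adj.items()
            if node not in rooted.labels
        )

    def test_internal_labels_and_support_dropped(self):
        t = parse_newick("((A:1,B:1)95:0.5,(C:1,D:1)inner:0.5);")
        assert t.leaf_set == {"A", "B", "C", "D"}

    def test_star_canonical(self):
        assert write_newick(parse_newick("(C,A,B);")) == "(A,B,C);"

    def test_permuted_input_byte_identical(self):
        variants = [
            "((A:1.5,B:2):1,(C:3,D:4):1);",
            "((D:4,C:3):1,(B:2,A:1.5):1);",
            "((C:3,D:4):1,(A:1.5,B:2):1);",
        ]
        outputs = {write_newick(parse_newick(v)) for v in variants}
        assert len(outputs) == 1

    def test_topology_only_tree_has_no_colons(self):
        assert ":" not in write_newick(parse_newick("((A,B),(C,D));"))

    def test_round_trip_preserves_splits_and_lengths(self):
        rng = np.random.default_rng(7)
        for n in (5, 8, 12):
            t = random_tree([f"t{i}" for i in range(n)], rng)
            back = parse_newick(write_newick(t))
            assert back.splits() == t.splits()
            for label in t.leaf_set:
                assert back.pendant_length(label) == pytest.approx(
                    t.pendant_length(label), abs=1e-12
                )


class TestPrune:
    def test_prune_to_star(self):
        t = prune_leaves(parse_newick("((A,B),(C,D));"), {"D"})
        assert t.leaf_set == {"A", "B", "C"}
        assert t.splits() == frozenset()

    def test_prune_nothing_is_identity(self):
        t = parse_newick("((A:1,B:2):1,(C:3,D:4):1);")
        assert write_newick(prune_leaves(t, set())) == write_newick(t)

    def test_suppression_sums_lengths(self):
        # ((A:1,B:1):1,(C:1,D:1):1) has central edge 2 after unrooting;
        # pruning C must leave D pendant 3 and preserve the A<->D path of 4
        t = prune_leaves(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"), {"C"})
        assert t.pendant_length("D") == pytest.approx(3.0)
        assert t.pendant_length("A") == pytest.approx(1.0)

    def test_prune_commutes(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = random_tree([f"t{i}" for i in range(8)], rng)
            one = prune_leaves(prune_leaves(t, {"t0"}), {"t3"})
            both = prune_leaves(t, {"t0", "t3"})
            assert one.splits() == both.splits()

    def test_prune_errors(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(TreeError):
            prune_leaves(t, {"Z"})
        with pytest.raises(TreeError):
            prune_leaves(t, {"A", "B"})


class TestRF:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(11)
        for n in (4, 7, 10):
            t = random_tree([f"t{i}" for i in range(n)], rng)
            assert rf_distance(t, t) == 0

    def test_hand_example(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2

    def test_differing_leaf_sets_rejected(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(TreeError):
            rf_distance(t1, t2)

    def test_matches_dendropy_oracle_on_random_pairs(self):
        rng = np.random.default_rng(20)
        for _ in range(40):
            n = int(rng.integers(6, 11))
            labels = [f"t{i}" for i in range(n)]
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            ours = rf_distance(t1, t2)
            oracle = dendropy_rf(write_newick(t1), write_newick(t2))
            assert ours == oracle

    def test_metric_properties(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(8)]
        trees = [random_tree(labels, rng) for _ in range(6)]
        for a in trees:
            for b in trees:
                assert rf_distance(a, b) == rf_distance(b, a)
        for a in trees:
            for b in trees:
                for c in trees:
                    assert rf_distance(a, c) <= (
                        rf_distance(a, b) + rf_distance(b, c)
                    )


class TestRestrict:
    def test_identical_leaf_sets_unchanged(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        r1, r2 = restrict_to_shared(t1, t2)
        assert r1.splits() == t1.splits() and r2.splits() == t2.splits()

    def test_extra_leaf_pruned(self):
        t1 = parse_newick("((A,B),(C,(D,X)));")
        t2 = parse_newick("((A,B),(C,D));")
        r1, r2 = restrict_to_shared(t1, t2)
        assert r1.leaf_set == r2.leaf_set == {"A", "B", "C", "D"}

    def test_output_leaf_sets_equal(self):
        rng = np.random.default_rng(9)
        t1 = random_tree([f"t{i}" for i in range(8)], rng)
        t2 = random_tree([f"t{i}" for i in range(4, 12)], rng)
        r1, r2 = restrict_to_shared(t1, t2)
        assert r1.leaf_set == r2.leaf_set == {"t4", "t5", "t6", "t7"}

    def test_too_few_shared(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,X),(Y,Z));")
        with pytest.raises(TreeError):
            restrict_to_shared(t1, t2)


class TestPlacement:
    def test_nested_example(self):
        p = placement(parse_newick("((A,B),(C,(D,E)));"), "E")
        assert p.neighbor_sets == frozenset(
            {frozenset({"D"}), frozenset({"A", "B", "C"})}
        )

    def test_star(self):
        p = placement(parse_newick("(A,B,C);"), "A")
        assert p.neighbor_sets == frozenset({frozenset({"B"}), frozenset({"C"})})

    def test_four_leaves(self):
        p = placement(parse_newick("((A,B),(C,D));"), "A")
        assert p.neighbor_sets == frozenset(
            {frozenset({"B"}), frozenset({"C", "D"})}
        )

    def test_unknown_leaf(self):
        with pytest.raises(TreeError):
            placement(parse_newick("(A,B,C);"), "Z")

    def test_invariant_under_round_trip(self):
        rng = np.random.default_rng(2)
        t = random_tree([f"t{i}" for i in range(9)], rng)
        back = parse_newick(write_newick(t))
        for label in t.leaf_set:
            assert placement(t, label) == placement(back, label)


class TestSamePlacement:
    def test_identical_trees(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        for label in t.leaf_set:
            assert same_placement(t, t, label)

    def test_differs_across_rearrangement(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert not same_placement(t1, t2, "A")

    def test_computed_on_shared_leaves(self):
        # extra leaves in t2 do not matter if the restriction agrees
        t1 = parse_newick("((A,B),(C,(D,E)));")
        t2 = parse_newick("((A,(B,X)),(C,(D,(E,Y))));")
        assert same_placement(t1, t2, "C")

    def test_insertion_at_other_edge_detected(self):
        backbone_left = parse_newick("(((X,A),B),(C,D));")
        backbone_right = parse_newick("((A,B),(C,(D,X)));")
        assert not same_placement(backbone_left, backbone_right, "X")

    def test_missing_focal_rejected(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(TreeError):
            same_placement(t1, t2, "E")


class TestMonophyly:
    def test_present_split(self):
        assert is_monophyletic(parse_newick("((A,B,C),(D,E));"), {"D", "E"})

    def test_absent_group(self):
        assert not is_monophyletic(
            parse_newick("((A,B),(C,(D,E)));"), {"A", "D"}
        )

    @pytest.mark.parametrize("group", [{"A"}, {"A", "B", "C", "D", "E"}])
    def test_trivial_groups(self, group):
        assert is_monophyletic(parse_newick("((A,B),(C,(D,E)));"), group)

    def test_complement_counts(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        assert is_monophyletic(t, {"C", "D", "E"})
        assert is_monophyletic(t, {"A", "B"})

    def test_unknown_label(self):
        with pytest.raises(TreeError):
            is_monophyletic(parse_newick("(A,B,C);"), {"A", "Z"})
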