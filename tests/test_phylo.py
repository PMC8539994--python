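import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from _oracles import random_additive_tree, tree_splits_and_lengths
from pantrait import cut_groups, neighbor_joining, pairwise_distance, root_with_outgroup
from pantrait.phylo import parse_newick


class TestPairwiseDistance:
    def test_identical_sequences_distance_zero(self):
        for model in ("p", "poisson"):
            dm = pairwise_distance({"a": "MKTAYIAK", "b": "MKTAYIAK"}, model=model)
            assert dm["a", "b"] == 0.0

    def test_p_distance_quarter(self):
        dm = pairwise_distance({"a": "AAAA", "b": "AAAT"})
        assert dm["a", "b"] == pytest.approx(0.25)

    def test_poisson_correction(self):
        dm = pairwise_distance({"a": "AAAA", "b": "AAAT"}, model="poisson")
        assert dm["a", "b"] == pytest.approx(-math.log(0.75))

    def test_poisson_rejects_saturated_pair(self):
        with pytest.raises(ValueError, match="infinite"):
            pairwise_distance({"a": "AAAA", "b": "WWWW"}, model="poisson")

    def test_matrix_satisfies_distance_axioms(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40)) for i in range(4)
        }
        dm = pairwise_distance(seqs)  # skbio validates symmetry and zero diagonal
        arr = dm.data
        assert np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0)
        assert (arr >= 0).all()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {c.taxon.label: c.edge.length for c in tree.seed_node.child_nodes()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0), "C": pytest.approx(3.0)}

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(np.array([[0, 5], [5, 0]], float), ids=list("AB"))
        tree = neighbor_joining(dm)
        total = sum(c.edge.length for c in tree.seed_node.child_nodes())
        assert total == pytest.approx(5.0)

    def test_four_taxon_additive_recovery(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:4))
        dm = DistanceMatrix(
            np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
            ids=list("ABCD"),
        )
        tree = neighbor_joining(dm)
        labels = list("ABCD")
        splits, lengths = tree_splits_and_lengths(tree, labels)
        assert splits == frozenset({frozenset({2, 3})})  # AB|CD
        assert lengths == pytest.approx([1.0, 1.0, 2.0, 3.0, 4.0])

    def test_random_additive_matrices_recovered(self, rng):
        for n in (5, 6, 7, 8):
            for _ in range(3):
                edges, lengths, D, true_splits = random_additive_tree(n, rng)
                labels = [f"L{i}" for i in range(n)]
                tree = neighbor_joining(DistanceMatrix(D, ids=labels))
                splits, got_lengths = tree_splits_and_lengths(tree, labels)
                assert splits == true_splits
                assert got_lengths == pytest.approx(sorted(lengths.values()))

    def test_tie_break_is_deterministic(self):
        # fully equidistant taxa: every Q is tied; smallest label pair joins first
        D = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(D, ids=list("ABCD"))
        t1 = neighbor_joining(dm).as_string(schema="newick")
        t2 = neighbor_joining(dm).as_string(schema="newick")
        assert t1 == t2
        assert "(A:" in t1 or ",A:" in t1


class TestRooting:
    def make_tree(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
            ids=list("ABCD"),
        )
        return neighbor_joining(dm)

    def test_outgroup_becomes_child_of_root(self):
        rooted, _ = root_with_outgroup(self.make_tree(), "D")
        children = rooted.seed_node.child_nodes()
        assert any(c.taxon is not None and c.taxon.label == "D" for c in children)

    def test_pendant_edge_split_at_midpoint(self):
        tree = self.make_tree()
        pendant = next(
            leaf.edge.length for leaf in tree.leaf_node_iter() if leaf.taxon.label == "D"
        )
        rooted, _ = root_with_outgroup(tree, "D")
        root_children = rooted.seed_node.child_nodes()
        assert sum(c.edge.length for c in root_children) == pytest.approx(pendant)
        d_edge = next(c.edge.length for c in root_children if c.taxon and c.taxon.label == "D")
        assert d_edge == pytest.approx(pendant / 2)

    def test_newick_round_trip(self):
        rooted, newick = root_with_outgroup(self.make_tree(), "C")
        back = parse_newick(newick)
        assert {l.taxon.label for l in back.leaf_node_iter()} == set("ABCD")
        orig = sorted((n.edge.length or 0.0) for n in rooted.preorder_node_iter() if n.parent_node)
        got = sorted((n.edge.length or 0.0) for n in back.preorder_node_iter() if n.parent_node)
        assert got == pytest.approx(orig)

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError, match="not a leaf"):
            root_with_outgroup(self.make_tree(), "Z")


class TestCutGroups:
    def rooted(self):
        rooted, _ = root_with_outgroup(
            neighbor_joining(
                DistanceMatrix(
                    np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
                    ids=list("ABCD"),
                )
            ),
            "D",
        )
        return rooted

    def test_threshold_above_diameter_single_group(self):
        groups = cut_groups(self.rooted(), 100.0)
        assert len(set(groups.values())) == 1

    def test_zero_threshold_all_singletons(self):
        groups = cut_groups(self.rooted(), 0.0)
        assert len(set(groups.values())) == 4

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            cut_groups(self.rooted(), -1.0)

    def test_groups_partition_leaves(self):
        groups = cut_groups(self.rooted(), 3.0)
        assert set(groups) == set("ABCD")

    def test_planted_clades_recovered(self, rng):
        # three tight clades far apart: pairwise within 0.2, between ~2
        from pantrait import pairwise_distance as _  # noqa: F401

        n_per = 3
        D = np.full((9, 9), 2.0)
        for c in range(3):
            for i in range(n_per):
                for j in range(n_per):
                    D[c * 3 + i, c * 3 + j] = 0.0 if i == j else 0.2
        labels = [f"c{c}_{i}" for c in range(3) for i in range(n_per)]
        tree = neighbor_joining(DistanceMatrix(D, ids=labels))
        rooted, _ = root_with_outgroup(tree, "c0_0")
        groups = cut_groups(rooted, 0.5)
        by_group: dict[int, set] = {}
        for leaf, grp in groups.items():
            by_group.setdefault(grp, set()).add(leaf.split("_")[0])
        clades = [v for v in by_group.values()]
        assert all(len(v) == 1 for v in clades)
        assert len({next(iter(v)) for v in clades if len(v) == 1}) == 3
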