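"""Neighbour joining, rooting, species collapsing and normalized RF."""

import dendropy
import numpy as np
import pytest

from kmerphylo.d2s_distance import DistanceMatrix
from kmerphylo.io_formats import ValidationError
from kmerphylo.trees import (
    PhyloTree,
    collapse_species,
    neighbor_joining,
    normalized_rf,
    root_with_outgroup,
    unroot,
)

from conftest import random_binary_tree, tree_path_distances


def dendropy_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    """Independent raw RF via dendropy's bipartition machinery."""
    ns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                           taxon_namespace=ns, preserve_underscores=True)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                           taxon_namespace=ns, preserve_underscores=True)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = DistanceMatrix(["A", "B", "C"],
                           np.array([[0.0, 3.0, 4.0],
                                     [3.0, 0.0, 5.0],
                                     [4.0, 5.0, 0.0]]))
        tree = neighbor_joining(m)
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_five_taxon_additive_recovery(self):
        truth = PhyloTree.from_newick("((A:1,B:2):3,(C:4,D:5):6,E:7);")
        labels, mat = tree_path_distances(truth)
        tree = neighbor_joining(DistanceMatrix(labels, mat))
        assert normalized_rf(tree, truth) == 0.0
        got_labels, got = tree_path_distances(tree)
        assert got_labels == labels
        np.testing.assert_allclose(got, mat, atol=1e-9)

    def test_additive_consistency_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            truth = random_binary_tree([f"t{i}" for i in range(n)], rng)
            labels, mat = tree_path_distances(truth)
            tree = neighbor_joining(DistanceMatrix(labels, mat))
            assert normalized_rf(tree, truth) == 0.0
            _, got = tree_path_distances(tree)
            np.testing.assert_allclose(got, mat, atol=1e-9)

    def test_matches_reference_nj_on_perturbed_matrices(self):
        """Same topology as scikit-bio's NJ on noisy 6-taxon matrices."""
        import io as _io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(1)
        for _ in range(10):
            truth = random_binary_tree([f"t{i}" for i in range(6)], rng)
            labels, mat = tree_path_distances(truth)
            noise = rng.uniform(-0.02, 0.02, size=mat.shape)
            noisy = mat + noise
            noisy = (noisy + noisy.T) / 2.0  # exactly symmetric
            np.fill_diagonal(noisy, 0.0)
            mine = neighbor_joining(DistanceMatrix(labels, noisy))
            ref = skbio_nj(SkbioDM(noisy, ids=labels))
            ref_tree = PhyloTree.from_newick(str(ref))
            assert normalized_rf(mine, ref_tree) == 0.0

    def test_asymmetric_or_bad_diagonal_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"],
                                            np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])))
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"],
                                            np.array([[0.5, 1, 2], [1, 0, 1], [2, 1, 0.0]])))

    def test_deterministic_under_ties(self):
        # four equidistant taxa: every Q entry ties; lexicographic pair joins
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        t1 = neighbor_joining(DistanceMatrix(list("DCBA"), m))
        t2 = neighbor_joining(DistanceMatrix(list("DCBA"), m))
        assert t1.to_newick() == t2.to_newick()


class TestRooting:
    def test_outgroup_pair(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(P1:1,P2:1):1,C:2);")
        rooted = root_with_outgroup(tree, ["P1", "P2"])
        assert rooted.rooted
        sides = [frozenset(PhyloTree(c).leaf_names()) for c in rooted.root.children]
        assert frozenset({"P1", "P2"}) in sides

    def test_single_leaf_outgroup_always_succeeds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            tree = random_binary_tree([f"x{i}" for i in range(7)], rng)
            rooted = root_with_outgroup(tree, ["x0"])
            sides = [frozenset(PhyloTree(c).leaf_names()) for c in rooted.root.children]
            assert frozenset({"x0"}) in sides

    def test_non_monophyletic_outgroup_rejected(self):
        tree = PhyloTree.from_newick("((A,P1),(B,P2),C);")
        with pytest.raises(ValidationError, match="monophyletic"):
            root_with_outgroup(tree, ["P1", "P2"])

    def test_root_unroot_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree = random_binary_tree([f"x{i}" for i in range(8)], rng)
            rooted = root_with_outgroup(tree, ["x3"])
            assert normalized_rf(unroot(rooted), tree) == 0.0


class TestCollapseSpecies:
    def test_cherry_collapsed_to_species_leaf(self):
        tree = PhyloTree.from_newick("((DtA,DtB),(X,Y));")
        smap = {"DtA": "D_trenchii", "DtB": "D_trenchii", "X": "SpX", "Y": "SpY"}
        out = collapse_species(tree, smap)
        assert sorted(out.leaf_names()) == ["D_trenchii", "SpX", "SpY"]

    def test_single_isolate_relabelled(self):
        tree = PhyloTree.from_newick("((A,B),C);")
        out = collapse_species(tree, {"A": "SpA", "B": "SpB", "C": "SpC"})
        assert sorted(out.leaf_names()) == ["SpA", "SpB", "SpC"]

    def test_non_monophyletic_species_keeps_isolates(self):
        tree = PhyloTree.from_newick("((A1,X),(A2,Y));")
        smap = {"A1": "SpA", "A2": "SpA", "X": "SpX", "Y": "SpY"}
        out = collapse_species(tree, smap)
        assert sorted(out.leaf_names()) == ["A1", "A2", "SpX", "SpY"]

    def test_leaf_count_drops_by_collapsed_clades(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n_species = int(rng.integers(3, 7))
            labels, smap = [], {}
            n_pairs = 0
            for s in range(n_species):
                if rng.random() < 0.5:
                    labels += [f"s{s}a", f"s{s}b"]
                    smap[f"s{s}a"] = smap[f"s{s}b"] = f"Sp{s}"
                    n_pairs += 1
                else:
                    labels.append(f"s{s}")
                    smap[f"s{s}"] = f"Sp{s}"
            if len(labels) < 4:
                continue
            # plant each isolate pair as a cherry: build tree over species then expand
            tree = random_binary_tree([f"Sp{s}" for s in range(n_species)], rng)

            def expand(node):
                if node.is_leaf:
                    members = [l for l in labels if smap[l] == node.name]
                    if len(members) == 2:
                        from kmerphylo.trees import Node
                        return Node(None, node.length,
                                    [Node(members[0], 0.1), Node(members[1], 0.1)])
                    node.name = members[0]
                    return node
                node.children = [expand(c) for c in node.children]
                return node

            expanded = PhyloTree(expand(tree.copy().root))
            out = collapse_species(expanded, smap)
            assert out.n_leaves == expanded.n_leaves - n_pairs

    def test_idempotent(self):
        tree = PhyloTree.from_newick("((DtA,DtB),(X,Y));")
        smap = {"DtA": "Dt", "DtB": "Dt", "X": "SpX", "Y": "SpY"}
        once = collapse_species(tree, smap)
        twice = collapse_species(once, smap)
        assert once.to_newick() == twice.to_newick()


class TestNormalizedRF:
    def test_identical_topologies_zero(self):
        rng = np.random.default_rng(5)
        tree = random_binary_tree([f"t{i}" for i in range(18)], rng)
        assert normalized_rf(tree, tree.copy()) == 0.0

    def test_no_shared_bipartitions_is_one(self):
        t1 = PhyloTree.from_newick("(((((A,B),C),D),E),F);")
        t2 = PhyloTree.from_newick("(((((A,D),F),B),E),C);")
        assert t1.bipartitions() & t2.bipartitions() == set()
        assert len(t1.bipartitions() ^ t2.bipartitions()) == 2 * (6 - 3)
        assert normalized_rf(t1, t2) == 1.0

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,B),(C,E));")
        with pytest.raises(ValidationError, match="differ"):
            normalized_rf(t1, t2)

    def test_matches_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(6)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(50):
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            raw = len(t1.bipartitions() ^ t2.bipartitions())
            assert raw == dendropy_rf(t1, t2)
            assert normalized_rf(t1, t2) == raw / (2 * (8 - 3))

    def test_isolate_branching_order_ignored(self):
        # same species topology, isolates swapped within a 3-isolate clade
        t1 = PhyloTree.from_newick("(((m1,(m2,m3)),X),(O,Y));")
        t2 = PhyloTree.from_newick("(((m3,(m1,m2)),X),(O,Y));")
        smap = {"m1": "SpM", "m2": "SpM", "m3": "SpM",
                "X": "SpX", "Y": "SpY", "O": "SpO"}
        assert normalized_rf(t1, t2, smap) == 0.0

    def test_species_nonmonophyletic_in_one_tree_not_collapsed(self):
        t1 = PhyloTree.from_newick("(((m1,m2),X),(Y,Z));")        # SpM monophyletic
        t2 = PhyloTree.from_newick("(((m1,X),m2),(Y,Z));")        # SpM broken up
        smap = {"m1": "SpM", "m2": "SpM", "X": "SpX", "Y": "SpY", "Z": "SpZ"}
        # joint collapsing must keep m1/m2 as isolates in both trees
        rf = normalized_rf(t1, t2, smap)
        assert rf > 0.0

    def test_rf_is_metric_like_on_fixed_leafset(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(7)]
        a, b = random_binary_tree(labels, rng), random_binary_tree(labels, rng)
        assert normalized_rf(a, b) == normalized_rf(b, a) >= 0.0
        assert normalized_rf(a, a) == 0.0
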