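import dendropy
import numpy as np
import pytest

from mitocongruence.tree import (
    PhyloTree,
    nni_neighbors,
    nni_move,
    perturb_tree,
    random_tree,
    sample_species_tree,
)

LABELS4 = ["a", "b", "c", "d"]


class TestRandomTree:
    def test_edge_counts(self):
        for n in (4, 7, 50):
            t = random_tree([f"t{i}" for i in range(n)], seed=1)
            assert len(t.edges()) == 2 * n - 3
            assert len(t.internal_edges()) == n - 3

    def test_four_taxa_uniform_over_topologies(self):
        """Sequential random addition is uniform over the 3 unrooted
        4-leaf topologies (multinomial 4-sigma band)."""
        counts = {}
        n = 3000
        for s in range(n):
            t = random_tree(LABELS4, seed=s)
            key = frozenset(t.bipartitions())
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        sd = np.sqrt(n * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - n / 3) < 4 * sd

    def test_deterministic(self):
        t1 = random_tree([f"t{i}" for i in range(20)], seed=7)
        t2 = random_tree([f"t{i}" for i in range(20)], seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_rejects_too_few_labels(self):
        with pytest.raises(ValueError):
            random_tree(["a", "b", "c"], seed=0)


class TestSpeciesTree:
    def test_shape_and_lengths(self):
        t = sample_species_tree(12, seed=3)
        assert t.n_leaves() == 12
        assert len(t.edges()) == 21
        assert all(e.length > 0 for e in t.edges())

    def test_deterministic(self):
        a = sample_species_tree(20, seed=7).to_newick()
        b = sample_species_tree(20, seed=7).to_newick()
        assert a == b

    def test_rejects_small(self):
        with pytest.raises(ValueError):
            sample_species_tree(3, seed=0)


class TestNni:
    def test_four_taxa_has_two_distinct_neighbors(self):
        t = random_tree(LABELS4, seed=1)
        nbs = nni_neighbors(t)
        assert len(nbs) == 2
        tops = {frozenset(x.bipartitions()) for x in nbs}
        tops.add(frozenset(t.bipartitions()))
        assert len(tops) == 3  # all three 4-leaf topologies

    def test_six_taxa_neighbor_set(self):
        t = random_tree([f"t{i}" for i in range(6)], seed=2)
        nbs = nni_neighbors(t)
        assert len(nbs) == 2 * (6 - 3)
        tops = {frozenset(x.bipartitions()) for x in nbs}
        assert len(tops) == 6  # pairwise distinct
        assert frozenset(t.bipartitions()) not in tops

    def test_involution(self):
        t = random_tree([f"t{i}" for i in range(8)], seed=3)
        once, _ = nni_move(t, 2, 1)
        # applying the corresponding inverse swap restores the topology
        candidates = nni_neighbors(once)
        assert any(c.rf_distance(t) == 0 for c in candidates)


class TestPerturb:
    def test_zero_moves_is_identity(self, tree6):
        assert perturb_tree(tree6, 0, "NNI", seed=1).rf_distance(tree6) == 0

    def test_single_nni_lands_in_neighbor_set(self):
        """One NNI from a 6-leaf caterpillar must be one of the
        exhaustively enumerated NNI neighbors."""
        cat = PhyloTree.from_newick(
            "(a:1,b:1,(c:1,(d:1,(e:1,f:1):1):1):1);"
        )
        neighbor_tops = {
            frozenset(x.bipartitions()) for x in nni_neighbors(cat)
        }
        for seed in range(10):
            p = perturb_tree(cat, 1, "NNI", seed=seed)
            assert frozenset(p.bipartitions()) in neighbor_tops

    @pytest.mark.parametrize("kind", ["NNI", "SPR"])
    def test_moves_usually_change_topology(self, kind):
        hits = 0
        for s in range(20):
            t = sample_species_tree(8, seed=s)
            p = perturb_tree(t, 3, kind, seed=100 + s)
            assert sorted(p.leaf_labels()) == sorted(t.leaf_labels())
            assert len(p.edges()) == len(t.edges())
            hits += t.rf_distance(p) > 0
        assert hits >= 19

    def test_deterministic(self, tree10):
        a = perturb_tree(tree10, 10, "NNI", seed=5).to_newick()
        b = perturb_tree(tree10, 10, "NNI", seed=5).to_newick()
        assert a == b

    def test_rejects_negative(self, tree6):
        with pytest.raises(ValueError):
            perturb_tree(tree6, -1, "NNI", seed=0)


class TestNewickAndRf:
    def test_round_trip(self, tree10):
        back = PhyloTree.from_newick(tree10.to_newick())
        assert back.rf_distance(tree10) == 0
        orig = {
            frozenset([c.name for c in n.children if c.is_leaf()])
            for n in tree10.postorder()
        }
        lens_a = sorted(e.length for e in tree10.edges())
        lens_b = sorted(e.length for e in back.edges())
        assert np.allclose(lens_a, lens_b, atol=1e-9)
        assert orig  # sanity

    def test_four_leaf_parse(self):
        t = PhyloTree.from_newick("(A:1,B:1,(C:1,D:1):1);")
        assert t.n_leaves() == 4
        assert len(t.internal_edges()) == 1

    def test_quoted_labels_survive(self):
        t = PhyloTree.from_newick(
            "('sp one':1,'sp two':1,('sp three':1,'sp four':1):0.5);"
        )
        back = PhyloTree.from_newick(t.to_newick())
        assert set(back.leaf_labels()) == {
            "sp one", "sp two", "sp three", "sp four"
        }

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("(A:1,:1,(C:1,D:1):1);")

    def test_rf_matches_dendropy(self):
        """Bipartition RF distance agrees with dendropy on random
        tree pairs."""
        for s in range(8):
            t1 = random_tree([f"t{i}" for i in range(9)], seed=s)
            t2 = random_tree([f"t{i}" for i in range(9)], seed=100 + s)
            tns = dendropy.TaxonNamespace()
            d1 = t1.to_dendropy(tns)
            d2 = t2.to_dendropy(tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(
                d1, d2
            )
            assert t1.rf_distance(t2) == expected

    def test_rf_rejects_leafset_mismatch(self, tree6, tree10):
        with pytest.raises(ValueError):
            tree6.rf_distance(tree10)
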