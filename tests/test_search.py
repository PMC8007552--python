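"""Tree search: exact == exhaustive, heuristic bounds, consensus."""

import random

import pytest

from mptree.engine import encode, tree_length
from mptree.search import (
    SearchConfig,
    TrivialInstanceError,
    branch_and_bound,
    exhaustive_search,
    heuristic_search,
    strict_consensus,
)
from mptree.simulate import decisive_matrix, random_tree
from mptree.trees import TreeTopology

from conftest import random_matrix


class TestExhaustive:
    def test_six_taxa_scores_all_105_topologies(self):
        rng = random.Random(0)
        m = random_matrix(rng, 6, 10)
        res = exhaustive_search(encode(m))
        assert res.search_log == ("topologies scored: 105",)
        assert res.proven_optimal

    def test_all_constant_matrix_every_topology_optimal(self):
        m = random_matrix(random.Random(0), 5, 4, symbols="0")
        res = exhaustive_search(encode(m))
        assert res.best_length == 0
        assert len(res.optimal_trees) == 15

    def test_too_many_taxa_refused(self):
        m = random_matrix(random.Random(0), 10, 4)
        with pytest.raises(ValueError, match="branch_and_bound"):
            exhaustive_search(encode(m))


class TestBranchAndBound:
    def test_matches_exhaustive_on_random_instances(self):
        rng = random.Random(42)
        for _ in range(8):
            n = rng.randint(5, 7)
            m = random_matrix(rng, n, rng.randint(10, 20))
            enc = encode(m)
            exact = exhaustive_search(enc)
            bb = branch_and_bound(enc)
            assert bb.best_length == exact.best_length
            assert set(bb.optimal_trees) == set(exact.optimal_trees)
            assert bb.proven_optimal

    def test_returned_lengths_are_real(self):
        rng = random.Random(3)
        m = random_matrix(rng, 7, 12)
        enc = encode(m)
        bb = branch_and_bound(enc)
        for t in bb.optimal_trees:
            assert tree_length(t, enc) == bb.best_length

    def test_suboptimal_margin_collects_near_optimal_trees(self):
        rng = random.Random(8)
        m = random_matrix(rng, 6, 12)
        enc = encode(m)
        res = branch_and_bound(enc, config=SearchConfig(suboptimal_margin=2))
        exact = exhaustive_search(enc)
        assert res.best_length == exact.best_length
        for length, tree in res.suboptimal_trees:
            assert res.best_length < length <= res.best_length + 2
            assert tree_length(tree, enc) == length

    def test_trivial_instance_refused(self):
        m = random_matrix(random.Random(0), 3, 5)
        with pytest.raises(TrivialInstanceError):
            branch_and_bound(encode(m))


class TestHeuristic:
    def test_never_beats_exact_and_often_matches(self):
        rng = random.Random(7)
        matched = 0
        for i in range(6):
            m = random_matrix(rng, 7, 15)
            enc = encode(m)
            exact = exhaustive_search(enc)
            heur = heuristic_search(
                enc, SearchConfig("heuristic", n_replicates=5, seed=i)
            )
            assert heur.best_length >= exact.best_length
            assert not heur.proven_optimal
            matched += heur.best_length == exact.best_length
        assert matched >= 5  # TBR from several starts is reliable at this size

    def test_four_taxa_equals_exhaustive(self):
        m = random_matrix(random.Random(1), 4, 10)
        enc = encode(m)
        heur = heuristic_search(enc, SearchConfig("heuristic", n_replicates=3, seed=0))
        assert heur.best_length == exhaustive_search(enc).best_length

    def test_seed_determinism(self):
        m = random_matrix(random.Random(2), 8, 15)
        enc = encode(m)
        a = heuristic_search(enc, SearchConfig("heuristic", n_replicates=4, seed=9))
        b = heuristic_search(enc, SearchConfig("heuristic", n_replicates=4, seed=9))
        assert a.best_length == b.best_length
        assert a.optimal_trees == b.optimal_trees

    def test_decisive_matrix_recovers_generating_topology(self):
        tree = random_tree(8, 4)
        enc = encode(decisive_matrix(tree))
        heur = heuristic_search(enc, SearchConfig("heuristic", n_replicates=3, seed=0))
        assert heur.optimal_trees == (tree,)


class TestStrictConsensus:
    def test_singleton_identity(self):
        t = TreeTopology.from_newick("((A,B),(C,(D,E)));")
        assert strict_consensus([t]) == t

    def test_incompatible_trees_collapse_to_star(self):
        a = TreeTopology.from_newick("((A,B),(C,D));")
        b = TreeTopology.from_newick("((A,C),(B,D));")
        cons = strict_consensus([a, b])
        assert cons.bipartitions() == set()

    def test_shared_cherry_retained(self):
        trees = [
            TreeTopology.from_newick("((A,B),(C,(D,E)));"),
            TreeTopology.from_newick("((A,B),(D,(C,E)));"),
            TreeTopology.from_newick("((A,B),(E,(C,D)));"),
        ]
        cons = strict_consensus(trees)
        assert cons.has_bipartition({"A", "B"})
        assert len(cons.bipartitions()) == 1
        assert not cons.is_binary()

    def test_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = random.Random(11)
        trees = [random_tree(7, rng.randint(0, 10**6)) for _ in range(4)]
        ours = strict_consensus(trees)
        tns = dendropy.TaxonNamespace()
        dlist = dendropy.TreeList(
            [
                dendropy.Tree.get(
                    data=t.newick(), schema="newick", taxon_namespace=tns
                )
                for t in trees
            ]
        )
        dcons = dlist.consensus(min_freq=1.0)
        theirs = TreeTopology.from_newick(
            dcons.as_string(schema="newick").replace("[&R] ", "")
        )
        assert ours.bipartitions() == theirs.bipartitions()

    def test_leaf_set_mismatch_rejected(self):
        a = TreeTopology.from_newick("((A,B),(C,D));")
        b = TreeTopology.from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="leaf sets"):
            strict_consensus([a, b])
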