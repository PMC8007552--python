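"""Bremer support: exact reverse-constrained search against the exhaustive
oracle, the tree-collection route, and the relative variant."""

import random

import pytest

from mptree.engine import encode
from mptree.search import branch_and_bound, exhaustive_search
from mptree.support import (
    bremer_absolute,
    bremer_relative,
    support_table,
)
from mptree.simulate import decisive_matrix, random_tree

from conftest import random_matrix


def oracle_bremer(enc, clade_labels):
    """Decay index by filtering a complete topology enumeration."""
    res = exhaustive_search(enc)
    best_with = None
    best_without = None
    # exhaustive_search only keeps optima; rescore every topology instead
    from mptree.search import _enumerate

    _, found, _, _ = _enumerate(enc, None, prune=False, margin=10**6,
                                start_order=list(range(enc.n_taxa)))
    clade = frozenset(clade_labels)
    for tree, length in found.items():
        leaves = tree.leaves
        anchor = min(leaves)
        key = clade if anchor not in clade else leaves - clade
        if key in tree.bipartitions():
            best_with = length if best_with is None else min(best_with, length)
        else:
            best_without = length if best_without is None else min(best_without, length)
    return res.best_length, best_without - res.best_length


class TestBremerAbsolute:
    def test_matches_exhaustive_oracle(self):
        rng = random.Random(31)
        for _ in range(5):
            n = rng.randint(5, 6)
            m = random_matrix(rng, n, rng.randint(8, 14), symbols="012?")
            enc = encode(m)
            bb = branch_and_bound(enc)
            clade = frozenset(rng.sample(m.taxa, 2))
            L, want = oracle_bremer(enc, clade)
            assert bb.best_length == L
            got = bremer_absolute(enc, L, clade)
            assert got == want

    def test_clade_absent_from_optimum_scores_zero(self):
        tree = random_tree(6, 2)
        m = decisive_matrix(tree)
        enc = encode(m)
        L = branch_and_bound(enc).best_length
        # pick two leaves that are NOT sisters in the generating tree
        leaves = sorted(tree.leaves)
        for pair in [(a, b) for a in leaves for b in leaves if a < b]:
            if not tree.has_bipartition(set(pair)):
                assert bremer_absolute(enc, L, set(pair)) == 0
                break

    def test_trivial_clades_rejected(self):
        m = random_matrix(random.Random(1), 6, 8)
        enc = encode(m)
        with pytest.raises(ValueError, match="non-trivial"):
            bremer_absolute(enc, 10, {m.taxa[0]})
        with pytest.raises(ValueError, match="non-trivial"):
            bremer_absolute(enc, 10, set(m.taxa))

    def test_decisive_cherry_has_positive_support(self):
        tree = random_tree(6, 5)
        m = decisive_matrix(tree)
        enc = encode(m)
        L = branch_and_bound(enc).best_length
        clade = next(iter(sorted(tree.bipartitions(), key=len)))
        assert bremer_absolute(enc, L, clade) >= 1


class TestBremerRelative:
    def test_clade_in_every_near_optimal_tree_undefined_within_margin(self):
        tree = random_tree(6, 7)
        m = decisive_matrix(tree)
        enc = encode(m)
        L = branch_and_bound(enc).best_length
        clade = min(tree.bipartitions(), key=len)
        # margin 0: only optimal trees, all of which contain the clade
        assert bremer_relative(enc, L, clade, margin=0) is None

    def test_unsupported_clade_scores_zero(self):
        rng = random.Random(13)
        m = random_matrix(rng, 6, 10, symbols="01")
        enc = encode(m)
        bb = branch_and_bound(enc)
        mpt = bb.optimal_trees[0]
        # a clade absent from the optimum: relative support 0
        leaves = sorted(mpt.leaves)
        for a in leaves:
            for b in leaves:
                if a < b and not mpt.has_bipartition({a, b}):
                    rel = bremer_relative(enc, bb.best_length, {a, b}, margin=0, mpt=mpt)
                    assert rel == 0.0
                    return

    def test_bounded_between_zero_and_one(self):
        rng = random.Random(19)
        m = random_matrix(rng, 6, 12, symbols="012")
        enc = encode(m)
        bb = branch_and_bound(enc)
        mpt = bb.optimal_trees[0]
        for clade in mpt.bipartitions():
            rel = bremer_relative(enc, bb.best_length, clade, margin=8, mpt=mpt)
            assert rel is None or 0.0 <= rel <= 1.0


class TestSupportTable:
    def test_four_taxa_single_record(self):
        m = random_matrix(random.Random(3), 4, 10, symbols="01")
        enc = encode(m)
        bb = branch_and_bound(enc)
        table = support_table(enc, bb)
        assert len(table) == 1

    def test_tree_set_route_matches_exact_on_small_instances(self):
        rng = random.Random(37)
        for _ in range(3):
            m = random_matrix(rng, 7, 15, symbols="012?")
            enc = encode(m)
            bb = branch_and_bound(enc)
            exact = support_table(enc, bb, method="exact")
            approx = support_table(enc, bb, method="tree_set", margin=8)
            got = {r.clade: r.absolute_bremer for r in approx}
            for r in exact:
                assert got[r.clade] == r.absolute_bremer

    def test_exact_route_requires_proven_optimum(self):
        from mptree.search import SearchConfig, heuristic_search

        m = random_matrix(random.Random(5), 6, 10)
        enc = encode(m)
        heur = heuristic_search(enc, SearchConfig("heuristic", n_replicates=2, seed=0))
        with pytest.raises(ValueError, match="proven"):
            support_table(enc, heur, method="exact")

    def test_records_cover_every_internal_branch(self):
        m = random_matrix(random.Random(8), 7, 14, symbols="012")
        enc = encode(m)
        bb = branch_and_bound(enc)
        table = support_table(enc, bb)
        assert {r.clade for r in table} == bb.optimal_trees[0].bipartitions()
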