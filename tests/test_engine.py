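"""Fitch scoring: oracle equivalence, root invariance, step bounds, CI/RI."""

import itertools
import random

import numpy as np
import pytest

from mptree.engine import (
    encode,
    fit_statistics,
    max_steps,
    min_steps,
    per_character_steps,
    tree_length,
)
from mptree.matrix_io import parse_matrix
from mptree.simulate import decisive_matrix, random_tree
from mptree.trees import TreeTopology

from conftest import random_matrix


def brute_force_length(tree: TreeTopology, matrix) -> int:
    """Minimum changes over every ancestral-state assignment, enumerated
    exhaustively (the independent oracle for Fitch)."""
    shape = tree.shape if not tree.rooted else tree.shape
    nodes = []

    def collect(s):
        if not isinstance(s, str):
            nodes.append(s)
            for k in s:
                collect(k)

    collect(shape)
    total = 0
    for c in range(1, matrix.n_characters + 1):
        states = sorted(matrix.observed_states(c)) or [0]
        cell = {
            t: (
                {int(matrix.cell(t, c))}
                if matrix.cell(t, c) not in "?-"
                else set(states)
            )
            for t in matrix.taxa
        }
        best = None
        for assign in itertools.product(states, repeat=len(nodes)):
            lookup = dict(zip(map(id, nodes), assign))

            def state_of(s):
                return lookup[id(s)] if not isinstance(s, str) else None

            cost = 0
            ok = True

            def walk(s, parent_state):
                nonlocal cost, ok
                if isinstance(s, str):
                    if parent_state in cell[s]:
                        return
                    # leaf resolves to the cheapest member of its set
                    cost += 1
                    return
                me = state_of(s)
                if parent_state is not None and me != parent_state:
                    cost += 1
                for k in s:
                    walk(k, me)

            walk(shape, None)
            if ok and (best is None or cost < best):
                best = cost
        total += best
    return total


class TestEncoding:
    def test_cell_bit_patterns(self):
        m = parse_matrix("A\t3\nB\t?\nC\t0\nD\t2", "tsv")
        enc = encode(m)
        assert enc.state_sets[0, 0] == 0b1000  # single state 3
        # ambiguous cell carries the observed-state mask {0,2,3}
        assert enc.state_sets[1, 0] == 0b1101
        assert enc.observed_masks[0] == 0b1101

    def test_study_fixture_grid_shape(self, study_enc):
        assert study_enc.state_sets.shape == (18, 64)
        assert len(study_enc.packed) == 18


class TestTreeLength:
    def test_three_taxa_two_states_forced_step(self):
        m = parse_matrix("A\t0\nB\t1\nC\t0", "tsv")
        t = TreeTopology.from_newick("(A,(B,C));")
        assert tree_length(t, encode(m)) == 1

    def test_constant_character_is_free(self):
        m = parse_matrix("A\t0\nB\t0\nC\t0\nD\t0", "tsv")
        t = TreeTopology.from_newick("((A,B),(C,D));")
        assert tree_length(t, encode(m)) == 0

    def test_leaf_mismatch_rejected(self):
        m = parse_matrix("A\t0\nB\t1\nC\t0", "tsv")
        t = TreeTopology.from_newick("(A,(B,X));")
        with pytest.raises(ValueError, match="leaves"):
            tree_length(t, encode(m))

    def test_matches_brute_force_oracle(self):
        rng = random.Random(5)
        for _ in range(12):
            n = rng.randint(4, 6)
            m = random_matrix(rng, n, rng.randint(3, 6), symbols="0123?")
            t = random_tree(n, rng.randint(0, 10**6), labels=m.taxa)
            assert tree_length(t, encode(m)) == brute_force_length(t, m)

    def test_root_invariance(self):
        from mptree.acctran import root_tree

        rng = random.Random(9)
        for _ in range(8):
            n = rng.randint(5, 9)
            m = random_matrix(rng, n, 12)
            t = random_tree(n, rng.randint(0, 10**6), labels=m.taxa)
            enc = encode(m)
            ref = tree_length(t, enc)
            for leaf in m.taxa:
                assert tree_length(root_tree(t, leaf), enc) == ref


class TestPerCharacterSteps:
    def test_sums_to_tree_length(self):
        rng = random.Random(17)
        for _ in range(10):
            n = rng.randint(4, 9)
            m = random_matrix(rng, n, 15)
            t = random_tree(n, rng.randint(0, 10**6), labels=m.taxa)
            enc = encode(m)
            assert per_character_steps(t, enc).sum() == tree_length(t, enc)

    def test_single_origin_character_on_study_matrix(self, study_enc, study_mpt):
        # character 1: one taxon with state 0, all others 1 -> exactly 1 step
        assert per_character_steps(study_mpt, study_enc)[0] == 1


class TestStepBounds:
    def test_min_steps_counts_observed_states(self, study_matrix):
        assert min_steps(study_matrix.column(41)) == 6  # seven observed states

    def test_max_steps_is_bush_value(self, study_matrix):
        # 18 scored taxa, most common state in 17 of them
        assert max_steps(study_matrix.column(1)) == 1

    def test_constant_and_empty_columns(self):
        assert min_steps(["0", "0", "0"]) == 0
        assert max_steps(["0", "0", "0"]) == 0
        assert min_steps(["?", "-"]) == 0
        assert max_steps(["?", "-"]) == 0

    def test_bounds_bracket_observed_steps(self):
        rng = random.Random(23)
        checked = 0
        for _ in range(40):
            n = rng.randint(4, 8)
            m = random_matrix(rng, n, 8)
            t = random_tree(n, rng.randint(0, 10**6), labels=m.taxa)
            s = per_character_steps(t, encode(m))
            for c in range(m.n_characters):
                lo = min_steps(m.column(c + 1))
                hi = max_steps(m.column(c + 1))
                assert lo <= s[c] <= hi
                checked += 1
        assert checked >= 100


class TestFitStatistics:
    def test_homoplasy_free_matrix_has_ci_one(self):
        t = random_tree(8, 3)
        m = decisive_matrix(t)
        enc = encode(m)
        fs = fit_statistics(t, enc, m)
        assert fs.ci == 1.0
        assert fs.ri == 1.0

    def test_display_rounding_half_away_from_zero(self):
        from mptree.engine import FitStatistics

        fs = FitStatistics(0, (), (), (), ci=0.455, ri=0.534)
        assert fs.ci_display == 46
        assert fs.ri_display == 53

    def test_informative_only_restriction(self, study_matrix, study_enc, study_mpt):
        full = fit_statistics(study_mpt, study_enc, study_matrix)
        restricted = fit_statistics(
            study_mpt, study_enc, study_matrix, informative_only=True
        )
        assert restricted.length == full.length
        assert restricted.ci < full.ci  # uninformative characters have s=m
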