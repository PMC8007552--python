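"""Matrix parsing, validation, round-trips and the bundled study fixture."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mptree.matrix_io import (
    CharacterMatrix,
    MatrixFormatError,
    load_study_fixture,
    parse_matrix,
    summarize,
    write_matrix,
)

DIALECTS = ("tsv", "tnt", "nexus")


class TestParsing:
    def test_minimal_tsv(self):
        m = parse_matrix("A\t0\nB\t1", "tsv")
        assert m.taxa == ("A", "B")
        assert m.observed_states(1) == {0, 1}

    def test_special_codes_mapped(self):
        m = parse_matrix("A\t?\t-\t3\nB\t0\t1\t2", "tsv")
        assert m.cells[0] == "?-3"

    def test_tnt_dialect_underscores_become_spaces(self):
        text = "xread\n'two taxa'\n3 2\nGenus_species 010\nOther_taxon 101\n;\n"
        m = parse_matrix(text, "tnt")
        assert m.taxa == ("Genus species", "Other taxon")
        assert m.cells == ("010", "101")

    def test_nexus_dialect(self):
        text = (
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=3;\n"
            'FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="0 1";\n'
            "MATRIX\nA_x 0?1\nB_y 1-0\n;\nEND;\n"
        )
        m = parse_matrix(text, "nexus")
        assert m.taxa == ("A x", "B y")
        assert m.cells[1] == "1-0"

    @pytest.mark.parametrize(
        "bad, err",
        [
            ("A\t0\t1\nB\t1", "ragged"),
            ("A\t0\nB\t9", "unknown symbol"),
            ("A\t0\nA\t1", "duplicate"),
        ],
    )
    def test_structural_errors(self, bad, err):
        with pytest.raises(MatrixFormatError, match=err):
            parse_matrix(bad, "tsv")

    def test_tnt_dimension_mismatch_rejected(self):
        with pytest.raises(MatrixFormatError, match="dimensions"):
            parse_matrix("xread\n2 2\nA 010\nB 101\n;\n", "tnt")


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", DIALECTS)
    def test_study_fixture_round_trips(self, dialect, study_matrix):
        assert parse_matrix(write_matrix(study_matrix, dialect), dialect) == study_matrix

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_random_matrices_round_trip_all_dialects(self, data):
        n = data.draw(st.integers(2, 8))
        c = data.draw(st.integers(1, 12))
        cells = tuple(
            "".join(data.draw(st.sampled_from("01234567?-")) for _ in range(c))
            for _ in range(n)
        )
        m = CharacterMatrix(taxa=tuple(f"tax {i}" for i in range(n)), cells=cells)
        for dialect in DIALECTS:
            assert parse_matrix(write_matrix(m, dialect), dialect) == m

    def test_missing_cell_serialized_as_question_mark(self):
        m = CharacterMatrix(taxa=("A", "B"), cells=("?", "0"))
        for dialect in DIALECTS:
            assert "?" in write_matrix(m, dialect)


class TestStudyFixture:
    def test_dimensions(self, study_matrix):
        assert study_matrix.n_taxa == 18
        assert study_matrix.n_characters == 64

    def test_taxon_order_starts_with_outgroup(self, study_matrix):
        assert study_matrix.taxa[0] == "Stygnus polyacanthus"

    def test_known_cells(self, study_matrix):
        # an unobservable cell and an inapplicable cell from the table
        assert study_matrix.cell("Pachyloides thorellii", 36) == "?"
        assert study_matrix.cell("Sadocus funestus", 41) == "-"

    def test_femur_pattern_character_has_seven_states(self, study_matrix):
        assert study_matrix.observed_states(41) == {0, 1, 2, 3, 4, 5, 6}

    def test_ocularium_character_states(self, study_matrix):
        col = study_matrix.column(1)
        assert study_matrix.observed_states(1) == {0, 1}
        assert col.count("0") == 1  # divided ocularium only in the outgroup

    def test_fixture_is_reloaded_identically(self, study_matrix):
        assert load_study_fixture() == study_matrix

    def test_bundled_tnt_copy_matches(self, study_matrix):
        from importlib import resources

        text = (
            resources.files("mptree.data")
            .joinpath("sadocus_table2.tnt")
            .read_text(encoding="utf-8")
        )
        assert parse_matrix(text, "tnt") == study_matrix


class TestSummarize:
    def test_constant_column_uninformative(self):
        m = parse_matrix("A\t0\nB\t0\nC\t0", "tsv")
        s = summarize(m)
        assert s.n_parsimony_informative == 0
        assert s.observed_states[0] == {0}

    def test_informative_needs_two_states_twice(self):
        # state 1 occurs once: variable but not parsimony-informative
        m = parse_matrix("A\t0\nB\t0\nC\t1", "tsv")
        assert summarize(m).n_parsimony_informative == 0
        m2 = parse_matrix("A\t0\nB\t0\nC\t1\nD\t1", "tsv")
        assert summarize(m2).n_parsimony_informative == 1

    def test_ambiguous_cells_counted_and_excluded(self):
        m = parse_matrix("A\t?\nB\t-\nC\t1", "tsv")
        s = summarize(m)
        assert (s.n_missing, s.n_inapplicable) == (1, 1)
        assert s.observed_states[0] == {1}

    def test_study_fixture_summary(self, study_matrix):
        s = summarize(study_matrix)
        assert (s.n_taxa, s.n_characters) == (18, 64)
        assert s.n_missing == 1
        assert s.n_inapplicable == 38
        assert s.n_parsimony_informative == 51
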