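"""Shared fixtures: the bundled study matrix and its (expensive) analysis
products are computed once per session."""

from __future__ import annotations

import random

import pytest

from mptree.acctran import acctran_reconstruct, root_tree
from mptree.engine import encode
from mptree.matrix_io import CharacterMatrix, load_study_fixture, parse_matrix
from mptree.search import SearchConfig, heuristic_search
from mptree.support import support_table

SADOCUS = frozenset(
    {
        "Sadocus asperatus",
        "Sadocus dilatatus",
        "Sadocus funestus",
        "Sadocus ingens",
        "Sadocus polyacanthus",
    }
)
NEOGONYLEPTES = frozenset({"Neogonyleptes docilis", "Neogonyleptes karschii"})
DISCO_ROEWERIA = frozenset({"Discocyrtus catharinensis", "Roeweria bittencourti"})
OUTGROUP = "Stygnus polyacanthus"


def random_matrix(
    rng: random.Random, n: int, c: int, symbols: str = "0123?-"
) -> CharacterMatrix:
    taxa = tuple(f"t{i}" for i in range(n))
    rows = "\n".join(
        f"{t}\t" + "\t".join(rng.choice(symbols) for _ in range(c)) for t in taxa
    )
    return parse_matrix(rows, "tsv")


@pytest.fixture(scope="session")
def study_matrix():
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_enc(study_matrix):
    return encode(study_matrix)


@pytest.fixture(scope="session")
def study_search(study_enc):
    """Heuristic search on the study matrix: ten TBR-swapped random
    addition sequences, which converge on a single best tree."""
    return heuristic_search(
        study_enc, SearchConfig("heuristic", n_replicates=10, swap="tbr", seed=1)
    )


@pytest.fixture(scope="session")
def study_mpt(study_search):
    return study_search.optimal_trees[0]


@pytest.fixture(scope="session")
def study_support(study_enc, study_search):
    return support_table(study_enc, study_search, method="tree_set", margin=6)


@pytest.fixture(scope="session")
def study_assignment(study_enc, study_mpt):
    return acctran_reconstruct(root_tree(study_mpt, OUTGROUP), study_enc)
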