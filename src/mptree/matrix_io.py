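"""Reading, validating and writing discrete morphological character matrices.

Matrices are taxa x characters tables of single states ``0``-``7`` plus the
two conventional special codes: ``?`` (missing: the character could not be
observed) and ``-`` (inapplicable: the character cannot logically be scored,
e.g. the shape of an absent structure).  Both special codes are treated as
full ambiguity over the character's observed states by every downstream
computation; for unordered (Fitch) parsimony an unobserved state can never
reduce tree length, so restricting the ambiguity set to observed states is
lossless.

Three text dialects are supported: TSV (one column per character, taxon
labels may contain spaces), TNT ``xread`` and NEXUS ``DATA`` blocks
(underscores replace internal whitespace in labels for the latter two).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CharacterMatrix",
    "MatrixSummary",
    "MatrixFormatError",
    "parse_matrix",
    "write_matrix",
    "load_study_fixture",
    "summarize",
]

#: Cell code for an unobservable character ("?").
MISSING = "?"
#: Cell code for a logically inapplicable character ("-").
INAPPLICABLE = "-"

_STATE_SYMBOLS = "01234567"
_VALID_CELLS = frozenset(_STATE_SYMBOLS) | {MISSING, INAPPLICABLE}

DIALECTS = ("tsv", "tnt", "nexus")


class MatrixFormatError(ValueError):
    """Raised for structurally invalid or unparseable matrix text."""


@dataclass(frozen=True)
class CharacterMatrix:
    """An immutable taxa x characters matrix of single-state cell codes.

    Parameters
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels.
    cells:
        One string of cell codes per taxon, ``cells[i][c]`` being the code
        of character ``c`` (0-based) for taxon ``i``.  Codes are drawn from
        ``0``-``7``, ``?`` and ``-``.
    character_labels, state_labels:
        Optional descriptive labels; ``state_labels`` maps
        ``(character_index, state)`` to text.
    """

    taxa: Tuple[str, ...]
    cells: Tuple[str, ...]
    character_labels: Optional[Tuple[str, ...]] = None
    state_labels: Optional[Dict[Tuple[int, int], str]] = field(default=None, hash=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.cells):
            raise MatrixFormatError(
                f"{len(self.taxa)} taxon labels but {len(self.cells)} rows"
            )
        seen = set()
        for label in self.taxa:
            if not label:
                raise MatrixFormatError("empty taxon label")
            if label in seen:
                raise MatrixFormatError(f"duplicate taxon label {label!r}")
            seen.add(label)
        if not self.cells:
            raise MatrixFormatError("matrix has no rows")
        width = len(self.cells[0])
        for label, row in zip(self.taxa, self.cells):
            if len(row) != width:
                raise MatrixFormatError(
                    f"ragged row for taxon {label!r}: "
                    f"{len(row)} cells, expected {width}"
                )
            for c, code in enumerate(row):
                if code not in _VALID_CELLS:
                    raise MatrixFormatError(
                        f"unknown symbol {code!r} at (taxon {label!r}, "
                        f"character {c + 1})"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0])

    def cell(self, taxon: str, character: int) -> str:
        """Cell code for ``taxon`` at 1-based ``character`` index."""
        i = self.taxa.index(taxon)
        if not 1 <= character <= self.n_characters:
            raise IndexError(f"character index {character} out of range")
        return self.cells[i][character - 1]

    def column(self, character: int) -> Tuple[str, ...]:
        """All cell codes of 1-based ``character``, in taxon order."""
        if not 1 <= character <= self.n_characters:
            raise IndexError(f"character index {character} out of range")
        return tuple(row[character - 1] for row in self.cells)

    def observed_states(self, character: int) -> frozenset:
        """Set of integer states scored in 1-based ``character``.

        MISSING and INAPPLICABLE cells are excluded.
        """
        return frozenset(
            int(code) for code in self.column(character) if code in _STATE_SYMBOLS
        )


@dataclass(frozen=True)
class MatrixSummary:
    """Descriptive statistics of a :class:`CharacterMatrix`."""

    n_taxa: int
    n_characters: int
    observed_states: Tuple[frozenset, ...]
    n_missing: int
    n_inapplicable: int
    n_parsimony_informative: int


def summarize(matrix: CharacterMatrix) -> MatrixSummary:
    """Summarize a matrix: per-character observed states and informativeness.

    A character is parsimony-informative iff at least two of its states are
    each scored in at least two taxa (ambiguous cells do not count).
    """
    observed = tuple(
        matrix.observed_states(c) for c in range(1, matrix.n_characters + 1)
    )
    n_missing = sum(row.count(MISSING) for row in matrix.cells)
    n_inapplicable = sum(row.count(INAPPLICABLE) for row in matrix.cells)
    n_informative = 0
    for c in range(1, matrix.n_characters + 1):
        counts: Dict[str, int] = {}
        for code in matrix.column(c):
            if code in _STATE_SYMBOLS:
                counts[code] = counts.get(code, 0) + 1
        if sum(1 for k in counts.values() if k >= 2) >= 2:
            n_informative += 1
    return MatrixSummary(
        n_taxa=matrix.n_taxa,
        n_characters=matrix.n_characters,
        observed_states=observed,
        n_missing=n_missing,
        n_inapplicable=n_inapplicable,
        n_parsimony_informative=n_informative,
    )


# ---------------------------------------------------------------------------
# parsing


def _label_out(label: str, dialect: str) -> str:
    return label if dialect == "tsv" else label.replace(" ", "_")


def _label_in(label: str, dialect: str) -> str:
    return label if dialect == "tsv" else label.replace("_", " ")


def _rows_to_matrix(rows: Sequence[Tuple[str, str]]) -> CharacterMatrix:
    if not rows:
        raise MatrixFormatError("no taxon rows found")
    return CharacterMatrix(
        taxa=tuple(r[0] for r in rows), cells=tuple(r[1] for r in rows)
    )


def _parse_tsv(text: str) -> CharacterMatrix:
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise MatrixFormatError(f"line {lineno}: expected taxon and cells")
        label, cells = fields[0].strip(), fields[1:]
        for f_ in cells:
            if len(f_.strip()) != 1:
                raise MatrixFormatError(
                    f"line {lineno}: cell {f_!r} is not a single symbol"
                )
        rows.append((label, "".join(f_.strip() for f_ in cells)))
    return _rows_to_matrix(rows)


def _parse_taxon_state_rows(lines: Sequence[str], dialect: str) -> CharacterMatrix:
    rows = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(f"cannot split row {line!r} into label + states")
        label, states = parts
        rows.append((_label_in(label, dialect), re.sub(r"\s+", "", states)))
    return _rows_to_matrix(rows)


def _parse_tnt(text: str) -> CharacterMatrix:
    body = text
    m = re.search(r"\bxread\b", body)
    if not m:
        raise MatrixFormatError("TNT input lacks an xread block")
    body = body[m.end():]
    # optional quoted title
    body = re.sub(r"^\s*'[^']*'", "", body, count=1)
    m = re.match(r"\s*(\d+)\s+(\d+)\s*\n", body)
    if not m:
        raise MatrixFormatError("TNT xread lacks 'nchar ntax' dimensions")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    body = body[m.end():]
    end = body.find(";")
    if end < 0:
        raise MatrixFormatError("TNT xread block not terminated by ';'")
    matrix = _parse_taxon_state_rows(body[:end].splitlines(), "tnt")
    if matrix.n_taxa != ntax or matrix.n_characters != nchar:
        raise MatrixFormatError(
            f"TNT dimensions ({nchar} chars, {ntax} taxa) do not match body "
            f"({matrix.n_characters} chars, {matrix.n_taxa} taxa)"
        )
    return matrix


def _parse_nexus(text: str) -> CharacterMatrix:
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise MatrixFormatError("NEXUS input must start with #NEXUS")
    m = re.search(r"MATRIX\s*\n(.*?);", text, re.S | re.I)
    if not m:
        raise MatrixFormatError("NEXUS input lacks a MATRIX command")
    matrix = _parse_taxon_state_rows(m.group(1).splitlines(), "nexus")
    dm = re.search(r"DIMENSIONS\s+NTAX\s*=\s*(\d+)\s+NCHAR\s*=\s*(\d+)", text, re.I)
    if dm:
        ntax, nchar = int(dm.group(1)), int(dm.group(2))
        if matrix.n_taxa != ntax or matrix.n_characters != nchar:
            raise MatrixFormatError(
                f"NEXUS DIMENSIONS ({ntax} taxa, {nchar} chars) do not match "
                f"matrix body ({matrix.n_taxa} taxa, {matrix.n_characters} chars)"
            )
    return matrix


def parse_matrix(text: str, dialect: str = "tsv") -> CharacterMatrix:
    """Parse serialized matrix ``text`` in the named ``dialect``.

    ``?`` is read as MISSING and ``-`` as INAPPLICABLE; cell order is
    preserved.  Raises :class:`MatrixFormatError` on ragged rows, unknown
    symbols or duplicate taxon labels.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "tsv":
        return _parse_tsv(text)
    if dialect == "tnt":
        return _parse_tnt(text)
    return _parse_nexus(text)


# ---------------------------------------------------------------------------
# writing


def write_matrix(matrix: CharacterMatrix, dialect: str = "tsv") -> str:
    """Serialize ``matrix`` so that :func:`parse_matrix` round-trips it."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "tsv":
        return "".join(
            label + "\t" + "\t".join(row) + "\n"
            for label, row in zip(matrix.taxa, matrix.cells)
        )
    pad = max(len(_label_out(t, dialect)) for t in matrix.taxa) + 2
    rows = "".join(
        _label_out(label, dialect).ljust(pad) + row + "\n"
        for label, row in zip(matrix.taxa, matrix.cells)
    )
    if dialect == "tnt":
        return (
            f"xread\n'{matrix.n_taxa} taxa, {matrix.n_characters} characters'\n"
            f"{matrix.n_characters} {matrix.n_taxa}\n{rows};\n"
        )
    return (
        "#NEXUS\nBEGIN DATA;\n"
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
        'FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="0 1 2 3 4 5 6 7";\n'
        f"MATRIX\n{rows};\nEND;\n"
    )


def load_study_fixture() -> CharacterMatrix:
    """Load the bundled 18-taxon, 64-character *Sadocus* study matrix.

    The matrix covers five ingroup *Sadocus* species and 13 outgroup
    harvestman taxa scored for 64 unordered morphological characters; the
    first taxon, *Stygnus polyacanthus*, is the conventional root.
    """
    try:
        text = (
            resources.files("mptree.data")
            .joinpath("sadocus_table2.tsv")
            .read_text(encoding="utf-8")
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise RuntimeError("bundled study matrix is missing from the package") from exc
    matrix = parse_matrix(text, "tsv")
    if matrix.n_taxa != 18 or matrix.n_characters != 64:  # pragma: no cover
        raise RuntimeError("bundled study matrix is corrupt")
    return matrix
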