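"""Equal-weights unordered (Fitch) parsimony scoring and fit indices.

Characters are unordered multistate with at most eight states, so every
cell is a subset of {0..7} held as an 8-bit mask.  Ambiguous cells
(missing or inapplicable) carry the character's full observed-state mask.

Tree length is computed with Fitch's downpass.  For speed inside tree
search all characters of a taxon are packed into one arbitrary-precision
integer using 16-bit lanes (state mask in the low byte of each lane), so a
Fitch node update is a handful of bitwise operations on whole rows; empty
intersections per lane are detected with an OR-cascade that cannot leak
across the spare high byte of a lane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .matrix_io import CharacterMatrix, MISSING, INAPPLICABLE
from .trees import TreeTopology

__all__ = [
    "EncodedMatrix",
    "FitStatistics",
    "encode",
    "tree_length",
    "per_character_steps",
    "min_steps",
    "max_steps",
    "fit_statistics",
]

_LANE = 16  # bits per character lane in the packed representation


@dataclass(frozen=True)
class EncodedMatrix:
    """A character matrix in search-ready form.

    ``state_sets[i, c]`` is the 8-bit state mask of taxon ``i`` for
    character ``c``; ambiguous cells equal ``observed_masks[c]``.
    ``packed[i]`` packs row ``i`` into 16-bit lanes, lane ``c`` holding
    ``state_sets[i, c]``.
    """

    taxa: Tuple[str, ...]
    n_characters: int
    state_sets: np.ndarray  # (n_taxa, n_char) uint8 bit masks
    observed_masks: np.ndarray  # (n_char,) uint8
    packed: Tuple[int, ...]
    lane_lsb: int  # bit 0 of every lane
    informative: np.ndarray  # (n_char,) bool

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"taxon {label!r} not in matrix") from None


def encode(matrix: CharacterMatrix) -> EncodedMatrix:
    """Encode a validated matrix into bit masks and packed rows.

    Raises ``ValueError`` if any character would need more than eight
    states (unreachable for the 0-7 symbol set of the text dialects).
    """
    n, c = matrix.n_taxa, matrix.n_characters
    state_sets = np.zeros((n, c), dtype=np.uint8)
    observed = np.zeros(c, dtype=np.uint8)
    counts = np.zeros((c, 8), dtype=np.int64)
    for j in range(c):
        col = matrix.column(j + 1)
        mask = 0
        for code in col:
            if code not in (MISSING, INAPPLICABLE):
                s = int(code)
                if s > 7:
                    raise ValueError("characters with more than 8 states unsupported")
                mask |= 1 << s
                counts[j, s] += 1
        observed[j] = mask
        ambiguous = mask if mask else 0xFF  # all-ambiguous column: any state
        for i, code in enumerate(col):
            if code in (MISSING, INAPPLICABLE):
                state_sets[i, j] = ambiguous
            else:
                state_sets[i, j] = 1 << int(code)
    lane_lsb = sum(1 << (_LANE * j) for j in range(c))
    packed = tuple(
        sum(int(state_sets[i, j]) << (_LANE * j) for j in range(c)) for i in range(n)
    )
    informative = (counts >= 2).sum(axis=1) >= 2
    return EncodedMatrix(
        taxa=matrix.taxa,
        n_characters=c,
        state_sets=state_sets,
        observed_masks=observed,
        packed=packed,
        lane_lsb=lane_lsb,
        informative=informative,
    )


# ---------------------------------------------------------------------------
# packed-row Fitch


def _nonempty_lane_mask(x: int, lane_lsb: int) -> int:
    """Bit 0 of each 16-bit lane set iff the lane's low byte is non-zero."""
    x |= x >> 4
    x |= x >> 2
    x |= x >> 1
    return x & lane_lsb


def fitch_combine(a: int, b: int, lane_lsb: int, n_char: int) -> Tuple[int, int]:
    """One Fitch downpass node update on packed rows.

    Returns ``(state_set, extra_steps)`` where the state set is the lane-wise
    intersection where non-empty, union elsewhere, and ``extra_steps`` counts
    the empty-intersection lanes.
    """
    inter = a & b
    nz = _nonempty_lane_mask(inter, lane_lsb)
    steps = n_char - nz.bit_count()
    full = (nz << 8) - nz  # 0xFF in every non-empty lane
    return (inter & full) | ((a | b) & ~full), steps


def _check_leaves(tree: TreeTopology, enc: EncodedMatrix) -> None:
    if tree.leaves != frozenset(enc.taxa):
        missing = frozenset(enc.taxa) - tree.leaves
        extra = tree.leaves - frozenset(enc.taxa)
        raise ValueError(
            f"tree leaves do not match matrix taxa "
            f"(missing from tree: {sorted(missing)}; unknown: {sorted(extra)})"
        )


def tree_length(tree: TreeTopology, enc: EncodedMatrix) -> int:
    """Fitch length of ``tree``: minimum total state changes over all
    characters.  Invariant to rooting and rotation."""
    _check_leaves(tree, enc)
    rows = {label: enc.packed[i] for i, label in enumerate(enc.taxa)}
    lsb, c = enc.lane_lsb, enc.n_characters
    total = 0

    def walk(shape) -> int:
        nonlocal total
        if isinstance(shape, str):
            return rows[shape]
        if len(shape) != 2:
            raise ValueError("tree must be binary for Fitch scoring")
        left = walk(shape[0])
        right = walk(shape[1])
        res, steps = fitch_combine(left, right, lsb, c)
        total += steps
        return res

    walk(tree.shape)
    return total


def per_character_steps(tree: TreeTopology, enc: EncodedMatrix) -> np.ndarray:
    """Fitch steps of every character on ``tree``; sums to the tree length."""
    _check_leaves(tree, enc)
    idx = {label: i for i, label in enumerate(enc.taxa)}
    steps = np.zeros(enc.n_characters, dtype=np.int64)

    def walk(shape) -> np.ndarray:
        if isinstance(shape, str):
            return enc.state_sets[idx[shape]]
        if len(shape) != 2:
            raise ValueError("tree must be binary for Fitch scoring")
        a = walk(shape[0])
        b = walk(shape[1])
        inter = a & b
        empty = inter == 0
        steps[empty] += 1
        return np.where(empty, a | b, inter)

    walk(tree.shape)
    return steps


# ---------------------------------------------------------------------------
# per-character step bounds and ensemble indices


def _column_counts(column: Sequence[str]) -> List[int]:
    counts = [0] * 8
    for code in column:
        if code not in (MISSING, INAPPLICABLE):
            counts[int(code)] += 1
    return counts


def min_steps(column: Sequence[str]) -> int:
    """Minimum conceivable steps of a character on any tree:
    (number of observed states) - 1.  Ambiguous cells are excluded."""
    observed = sum(1 for k in _column_counts(column) if k > 0)
    return max(0, observed - 1)


def max_steps(column: Sequence[str]) -> int:
    """Maximum steps of a character on any tree (the star-tree / bush value):
    (number of scored taxa) - (frequency of the most common state)."""
    counts = _column_counts(column)
    scored = sum(counts)
    if scored == 0:
        return 0
    return scored - max(counts)


@dataclass(frozen=True)
class FitStatistics:
    """Tree length and ensemble consistency / retention indices.

    ``ci = sum(m_c) / sum(s_c)`` and ``ri = (sum(g_c) - sum(s_c)) /
    (sum(g_c) - sum(m_c))`` where ``m_c``, ``s_c`` and ``g_c`` are the
    per-character minimum, observed and maximum steps.  Display forms are
    integer percentages, rounded half away from zero.
    """

    length: int
    steps: Tuple[int, ...]
    minima: Tuple[int, ...]
    maxima: Tuple[int, ...]
    ci: float
    ri: float

    @staticmethod
    def _display(value: float) -> int:
        scaled = 100.0 * value
        return int(math.floor(scaled + 0.5)) if scaled >= 0 else -int(
            math.floor(-scaled + 0.5)
        )

    @property
    def ci_display(self) -> int:
        return self._display(self.ci)

    @property
    def ri_display(self) -> int:
        return self._display(self.ri)

    def to_dict(self) -> Dict[str, object]:
        return {
            "length": self.length,
            "ci": self.ci,
            "ri": self.ri,
            "ci_display": self.ci_display,
            "ri_display": self.ri_display,
            "per_character_steps": list(self.steps),
            "per_character_min": list(self.minima),
            "per_character_max": list(self.maxima),
        }


def fit_statistics(
    tree: TreeTopology,
    enc: EncodedMatrix,
    matrix: CharacterMatrix,
    informative_only: bool = False,
) -> FitStatistics:
    """Compute length, per-character step decomposition and ensemble CI/RI.

    By default all characters enter the ensemble sums (the convention of
    the common parsimony programs); ``informative_only`` restricts the sums
    to parsimony-informative characters.
    """
    s = per_character_steps(tree, enc)
    m = np.array(
        [min_steps(matrix.column(c + 1)) for c in range(matrix.n_characters)],
        dtype=np.int64,
    )
    g = np.array(
        [max_steps(matrix.column(c + 1)) for c in range(matrix.n_characters)],
        dtype=np.int64,
    )
    length = int(s.sum())
    keep = enc.informative if informative_only else np.ones(len(s), dtype=bool)
    ssum, msum, gsum = int(s[keep].sum()), int(m[keep].sum()), int(g[keep].sum())
    ci = msum / ssum if ssum else 1.0
    ri = (gsum - ssum) / (gsum - msum) if gsum != msum else 1.0
    return FitStatistics(
        length=length,
        steps=tuple(int(x) for x in s),
        minima=tuple(int(x) for x in m),
        maxima=tuple(int(x) for x in g),
        ci=ci,
        ri=ri,
    )
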