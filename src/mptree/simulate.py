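"""Synthetic trees and discrete character matrices with known ground truth.

Characters evolve root-to-tips on a known topology by a per-branch switch
process: the root draws a uniform state and every branch switches to a
uniformly chosen *different* state with a fixed probability.  The switch
probability directly tunes homoplasy (0 gives clean hierarchical data,
high values approach noise), which is what a parsimony estimator needs to
be tested against; missing (``?``) and inapplicable (``-``) cells are then
injected at configurable fractions.  All randomness flows from a single
integer seed, so identical configurations are byte-identical.

``decisive_matrix`` builds the fully clean special case — one binary
character per internal branch — for which parsimony search must recover
the generating topology exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .matrix_io import CharacterMatrix, INAPPLICABLE, MISSING
from .trees import TreeTopology

__all__ = [
    "SimulationConfig",
    "random_tree",
    "simulate_matrix",
    "degrade_matrix",
    "decisive_matrix",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the seed fully determines the output."""

    n_taxa: int
    n_characters: int
    n_states: int = 2
    change_probability: float = 0.1
    missing_fraction: float = 0.0
    inapplicable_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_states <= 8:
            raise ValueError("n_states must be in 2..8")
        for name in ("change_probability", "missing_fraction", "inapplicable_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.missing_fraction + self.inapplicable_fraction > 1.0:
            raise ValueError("missing + inapplicable fractions exceed 1")


def _default_labels(n: int) -> Tuple[str, ...]:
    width = len(str(n))
    return tuple(f"t{str(i + 1).zfill(width)}" for i in range(n))


def random_tree(
    n_taxa: int, seed: int, labels: Optional[Sequence[str]] = None
) -> TreeTopology:
    """A uniformly distributed unrooted binary topology on ``n_taxa`` leaves.

    Sequential random attachment: each new leaf subdivides a uniformly
    chosen branch, which yields the uniform distribution over labelled
    unrooted binary shapes.
    """
    if n_taxa < 4:
        raise ValueError("random_tree needs at least 4 taxa")
    labels = tuple(labels) if labels is not None else _default_labels(n_taxa)
    if len(labels) != n_taxa:
        raise ValueError("label count does not match n_taxa")
    rng = np.random.default_rng(seed)
    # adjacency over ints: leaves 0..n-1, internals from n
    adj: Dict[int, List[int]] = {i: [] for i in range(3)}
    center = n_taxa
    adj[center] = [0, 1, 2]
    for i in range(3):
        adj[i] = [center]
    edges = [(0, center), (1, center), (2, center)]
    next_internal = n_taxa + 1
    for leaf in range(3, n_taxa):
        a, b = edges[rng.integers(len(edges))]
        w = next_internal
        next_internal += 1
        adj[a].remove(b)
        adj[b].remove(a)
        adj[w] = [a, b, leaf]
        adj[a].append(w)
        adj[b].append(w)
        adj[leaf] = [w]
        edges.remove((a, b))
        edges.extend([(a, w), (b, w), (leaf, w)])

    def shape(v: int, parent: int):
        nbrs = [u for u in adj[v] if u != parent]
        if not nbrs:
            return labels[v]
        kids = tuple(shape(u, v) for u in nbrs)
        return kids if len(kids) > 1 else kids[0]

    return TreeTopology((labels[0], shape(adj[0][0], 0)), rooted=False)


def simulate_matrix(tree: TreeTopology, config: SimulationConfig) -> CharacterMatrix:
    """Evolve ``config.n_characters`` unordered characters on ``tree``.

    The (arbitrary) root sits on the pendant branch of the first leaf;
    root placement does not affect the distribution of patterns, because
    the switch process is symmetric among states.
    """
    if tree.n_leaves != config.n_taxa:
        raise ValueError(
            f"tree has {tree.n_leaves} leaves but config.n_taxa={config.n_taxa}"
        )
    rng = np.random.default_rng(config.seed)
    rooted = tree if tree.rooted else TreeTopology(tree.shape, rooted=True)
    leaf_states: Dict[str, List[int]] = {label: [] for label in sorted(tree.leaves)}
    k = config.n_states

    def evolve(shape, state: int) -> None:
        # one branch above `shape`: switch with the configured probability
        if rng.random() < config.change_probability:
            offset = 1 + int(rng.integers(k - 1))
            state = (state + offset) % k
        if isinstance(shape, str):
            leaf_states[shape].append(state)
        else:
            for kid in shape:
                evolve(kid, state)

    for _ in range(config.n_characters):
        root_state = int(rng.integers(k))
        for kid in rooted.shape:
            evolve(kid, root_state)

    taxa = tuple(sorted(tree.leaves))
    cells = tuple("".join(str(s) for s in leaf_states[t]) for t in taxa)
    matrix = CharacterMatrix(taxa=taxa, cells=cells)
    if config.missing_fraction or config.inapplicable_fraction:
        matrix = degrade_matrix(
            matrix,
            config.missing_fraction,
            config.inapplicable_fraction,
            seed=int(rng.integers(2**31)),
        )
    return matrix


def degrade_matrix(
    matrix: CharacterMatrix,
    missing_fraction: float,
    inapplicable_fraction: float,
    seed: int,
) -> CharacterMatrix:
    """Replace uniformly chosen cells by ``?`` / ``-`` at the given fractions."""
    if missing_fraction < 0 or inapplicable_fraction < 0:
        raise ValueError("fractions must be non-negative")
    if missing_fraction + inapplicable_fraction > 1.0:
        raise ValueError("fractions sum above 1: matrix would be over-replaced")
    if missing_fraction == 0 and inapplicable_fraction == 0:
        return matrix
    rng = np.random.default_rng(seed)
    n, c = matrix.n_taxa, matrix.n_characters
    total = n * c
    n_miss = int(round(total * missing_fraction))
    n_inap = int(round(total * inapplicable_fraction))
    chosen = rng.choice(total, size=min(total, n_miss + n_inap), replace=False)
    grid = [list(row) for row in matrix.cells]
    for j, flat in enumerate(chosen):
        i, cc = divmod(int(flat), c)
        grid[i][cc] = MISSING if j < n_miss else INAPPLICABLE
    return CharacterMatrix(
        taxa=matrix.taxa,
        cells=tuple("".join(row) for row in grid),
        character_labels=matrix.character_labels,
        state_labels=matrix.state_labels,
    )


def decisive_matrix(tree: TreeTopology) -> CharacterMatrix:
    """One clean binary character per internal branch of ``tree``.

    Each non-trivial bipartition gets a character scoring its smaller side
    1 and the rest 0, so the matrix is homoplasy-free and parsimony
    search recovers exactly the generating topology.
    """
    taxa = tuple(sorted(tree.leaves))
    bips = sorted(tree.unroot().bipartitions(), key=lambda s: (len(s), sorted(s)))
    if not bips:
        raise ValueError("tree has no internal branches")
    cells = tuple(
        "".join("1" if t in side else "0" for side in bips) for t in taxa
    )
    return CharacterMatrix(taxa=taxa, cells=cells)
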