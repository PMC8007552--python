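"""Absolute and relative Bremer (decay) support for clades.

The absolute Bremer support of a clade is the extra length of the best
tree that does *not* contain the clade as a bipartition, relative to the
optimal length.  Two routes are provided:

* ``exact`` — reverse-constrained branch-and-bound: the enumeration
  kernel tracks, for every clade of interest, the shortest completion
  lacking it, seeded by an SPR-scan upper bound.  Exact but exponential;
  practical for moderate matrices.
* ``tree_set`` — the classic decay-script procedure: collect near-optimal
  trees by branch swapping around the optima while retaining everything
  within a margin, then take, per clade, the best collected tree lacking
  it, refined by a constrained hill-climb.  Values are upper bounds that
  converge to the exact decay index as the collection grows; this is how
  Bremer support is routinely computed for matrices beyond exact reach.

Relative Bremer support follows the relative-fit-difference convention:
with per-character steps ``s`` on the optimal tree and ``s'`` on the best
counter-tree, ``F`` sums the step differences of characters favoring the
clade (``s' > s``) and ``C`` those contradicting it; the relative support
is ``(F - C) / F``, i.e. absolute support scaled by the amount of favoring
evidence, in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .engine import EncodedMatrix, per_character_steps
from .search import (
    SearchResult,
    _adj_length,
    _adj_topology,
    _apply_spr,
    _apply_tbr,
    _run_core,
    _spr_moves,
    _tbr_extra_moves,
)
from .trees import TreeTopology

__all__ = [
    "SupportRecord",
    "bremer_absolute",
    "bremer_relative",
    "support_table",
]


@dataclass(frozen=True)
class SupportRecord:
    """Bremer support of one internal branch (clade) of the optimal tree."""

    clade: FrozenSet[str]
    absolute_bremer: int
    relative_bremer: Optional[float]


def _clade_indices(enc: EncodedMatrix, clade: Iterable[str]) -> FrozenSet[int]:
    labels = frozenset(clade)
    unknown = labels - frozenset(enc.taxa)
    if unknown:
        raise ValueError(f"unknown taxa in clade: {sorted(unknown)}")
    if len(labels) < 2 or len(labels) > enc.n_taxa - 2:
        raise ValueError(
            "Bremer support needs a non-trivial bipartition: "
            f"2 <= |clade| <= n-2, got {len(labels)} of {enc.n_taxa}"
        )
    return frozenset(enc.taxon_index(t) for t in labels)


def _tree_adjacency(tree: TreeTopology, enc: EncodedMatrix) -> Dict[int, List[int]]:
    """Unrooted adjacency over taxon indices (internal ids from n up)."""
    counter = [enc.n_taxa]
    adj: Dict[int, List[int]] = {}

    def add_edge(a: int, b: int) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def build(shape) -> int:
        if isinstance(shape, str):
            return enc.taxon_index(shape)
        node = counter[0]
        counter[0] += 1
        adj.setdefault(node, [])
        for k in shape:
            add_edge(node, build(k))
        return node

    shape = tree.unroot().shape
    anchor, rest = shape
    top = build(rest)
    add_edge(enc.taxon_index(anchor), top)
    return adj


def _counter_upper_bounds(
    enc: EncodedMatrix,
    trees: Sequence[TreeTopology],
    clades: Sequence[FrozenSet[str]],
) -> Dict[FrozenSet[str], int]:
    """Upper-bound the best counter-tree length per clade by scanning the
    SPR neighborhoods of the given optimal trees."""
    best: Dict[FrozenSet[str], int] = {}
    for tree in trees:
        adj = _tree_adjacency(tree, enc)
        for move in _spr_moves(adj):
            cand = _apply_spr(adj, *move)
            topo = _adj_topology(cand, enc)
            length = _adj_length(cand, enc)
            bips = topo.bipartitions()
            leaves = topo.leaves
            anchor = min(leaves)
            for clade in clades:
                key = clade if anchor not in clade else leaves - clade
                if key not in bips:
                    if clade not in best or length < best[clade]:
                        best[clade] = length
    return best


def _exact_counter_lengths(
    enc: EncodedMatrix,
    L_opt: int,
    clades: Sequence[FrozenSet[str]],
    ceiling: int,
) -> List[Tuple[Optional[int], Optional[TreeTopology]]]:
    idx_clades = [_clade_indices(enc, c) for c in clades]
    res = _run_core(
        enc, ceiling=ceiling, best0=L_opt, margin=ceiling - L_opt, clades=idx_clades
    )
    return res["counters"]


def bremer_absolute(
    enc: EncodedMatrix,
    L_opt: int,
    clade: Iterable[str],
    method: str = "exact",
    mpt: Optional[TreeTopology] = None,
    margin: int = 6,
) -> int:
    """Decay index of ``clade``: minimum length over binary trees not
    showing the clade as a bipartition, minus the optimal length ``L_opt``.

    ``method='exact'`` proves the value by reverse-constrained search;
    ``method='tree_set'`` takes it from a near-optimal tree collection
    around ``mpt`` (an upper bound that converges to the exact index).
    Clades absent from some optimal tree get support 0.
    """
    labels = frozenset(clade)
    _clade_indices(enc, labels)  # validation
    if method == "exact":
        length, _ = _best_counter(enc, L_opt, labels)
        return length - L_opt
    if method != "tree_set":
        raise ValueError(f"unknown method {method!r}")
    if mpt is None:
        from .search import SearchConfig, heuristic_search

        mpt = heuristic_search(
            enc, SearchConfig("heuristic", n_replicates=5, seed=0)
        ).optimal_trees[0]
    found = _tree_set_counters(enc, [mpt], [labels], L_opt, margin)
    if labels not in found:
        raise RuntimeError(
            f"no counter-tree within margin {margin}; increase the margin"
        )
    return found[labels][0] - L_opt


def _best_counter(
    enc: EncodedMatrix, L_opt: int, clade: FrozenSet[str]
) -> Tuple[int, TreeTopology]:
    """Exact best tree lacking ``clade``; seeded by an SPR-scan bound."""
    # a cheap counter-tree from the SPR neighborhood of a good tree
    from .search import SearchConfig, heuristic_search

    base = heuristic_search(enc, SearchConfig("heuristic", n_replicates=3, seed=0))
    ubs = _counter_upper_bounds(enc, base.optimal_trees[:1], [clade])
    ceiling = ubs.get(clade, L_opt + enc.n_characters)
    counters = _exact_counter_lengths(enc, L_opt, [clade], ceiling)
    length, tree = counters[0]
    if length is None:  # pragma: no cover - SPR scan always finds a counter
        raise RuntimeError("no counter-tree found under the search ceiling")
    return length, tree


def bremer_relative(
    enc: EncodedMatrix,
    L_opt: int,
    clade: Iterable[str],
    margin: int,
    mpt: Optional[TreeTopology] = None,
) -> Optional[float]:
    """Relative Bremer support from trees within ``margin`` steps of optimal.

    Returns None (undefined) when no counter-tree exists within the margin.
    The value is ``(F - C) / F`` over per-character step differences between
    the best counter-tree and the optimal tree (see module docstring).
    """
    labels = frozenset(clade)
    _clade_indices(enc, labels)
    counters = _exact_counter_lengths(enc, L_opt, [labels], L_opt + margin)
    length, counter_tree = counters[0]
    if length is None:
        return None
    if mpt is None:
        from .search import branch_and_bound

        mpt = branch_and_bound(enc).optimal_trees[0]
    return _relative_from_trees(enc, mpt, counter_tree)


def _relative_from_trees(
    enc: EncodedMatrix, mpt: TreeTopology, counter: TreeTopology
) -> Optional[float]:
    s_with = per_character_steps(mpt, enc)
    s_without = per_character_steps(counter, enc)
    d = s_without.astype(np.int64) - s_with.astype(np.int64)
    favoring = int(d[d > 0].sum())
    contradicting = int(-d[d < 0].sum())
    if favoring == 0:
        return 0.0
    return (favoring - contradicting) / favoring


def _lacks_clade(tree: TreeTopology, clade: FrozenSet[str]) -> bool:
    leaves = tree.leaves
    anchor = min(leaves)
    key = clade if anchor not in clade else leaves - clade
    return key not in tree.bipartitions()


def _tree_set_counters(
    enc: EncodedMatrix,
    mpt_trees: Sequence[TreeTopology],
    clades: Sequence[FrozenSet[str]],
    L_opt: int,
    margin: int,
) -> Dict[FrozenSet[str], Tuple[int, TreeTopology]]:
    """Best counter-tree per clade from a near-optimal tree collection.

    Branch swapping (SPR + TBR) around the optimal trees retains every
    candidate within ``margin`` steps; each clade's provisional counter is
    then improved by a hill-climb over TBR neighbors restricted to trees
    still lacking the clade.
    """
    ceiling = L_opt + margin
    pool: Dict[TreeTopology, int] = {}

    def sweep(tree: TreeTopology) -> None:
        adj = _tree_adjacency(tree, enc)
        for move in _spr_moves(adj):
            cand = _apply_spr(adj, *move)
            length = _adj_length(cand, enc)
            if length <= ceiling:
                topo = _adj_topology(cand, enc)
                if topo not in pool or length < pool[topo]:
                    pool[topo] = length
        for move in _tbr_extra_moves(adj):
            cand = _apply_tbr(adj, *move)
            length = _adj_length(cand, enc)
            if length <= ceiling:
                topo = _adj_topology(cand, enc)
                if topo not in pool or length < pool[topo]:
                    pool[topo] = length

    for tree in mpt_trees:
        pool[tree] = L_opt
        sweep(tree)

    out: Dict[FrozenSet[str], Tuple[int, TreeTopology]] = {}
    for clade in clades:
        counters = [(l, t) for t, l in pool.items() if _lacks_clade(t, clade)]
        if not counters:
            continue
        best_len, best_tree = min(counters, key=lambda x: x[0])
        # constrained hill-climb: only counter trees, strictly shorter
        improved = True
        while improved and best_len > L_opt:
            improved = False
            adj = _tree_adjacency(best_tree, enc)
            for move in _spr_moves(adj):
                cand = _apply_spr(adj, *move)
                length = _adj_length(cand, enc)
                if length < best_len:
                    topo = _adj_topology(cand, enc)
                    if _lacks_clade(topo, clade):
                        best_len, best_tree = length, topo
                        improved = True
                        break
        out[clade] = (best_len, best_tree)
    return out


def support_table(
    enc: EncodedMatrix,
    search_result: SearchResult,
    method: str = "auto",
    margin: int = 6,
) -> List[SupportRecord]:
    """Absolute and relative Bremer support for every internal branch of
    the optimal tree.

    Requires a proven-optimal (or believed-optimal heuristic)
    :class:`SearchResult`; support is defined relative to the optimum.
    ``method`` is ``exact`` (one reverse-constrained exact search resolves
    all branches), ``tree_set`` (near-optimal collection, the decay-script
    procedure) or ``auto`` (exact up to 12 taxa, tree_set beyond).
    """
    if not search_result.optimal_trees:
        raise ValueError("empty search result")
    if method not in ("auto", "exact", "tree_set"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if enc.n_taxa <= 12 else "tree_set"
    if method == "exact" and not search_result.proven_optimal:
        raise ValueError(
            "exact support needs a proven optimal search result "
            "(run branch_and_bound or exhaustive_search)"
        )
    L_opt = search_result.best_length
    mpt = search_result.optimal_trees[0]
    clades = sorted(mpt.bipartitions(), key=lambda s: (len(s), sorted(s)))
    if not clades:
        return []

    # clades missing from another optimal tree have support 0 outright
    zero: Dict[FrozenSet[str], TreeTopology] = {}
    for other in search_result.optimal_trees[1:]:
        bips = other.bipartitions()
        for clade in clades:
            if clade not in bips and clade not in zero:
                zero[clade] = other
    pending = [c for c in clades if c not in zero]

    counter_len: Dict[FrozenSet[str], int] = {}
    counter_tree: Dict[FrozenSet[str], TreeTopology] = {}
    for clade, tree in zero.items():
        counter_len[clade] = L_opt
        counter_tree[clade] = tree
    if pending and method == "exact":
        ubs = _counter_upper_bounds(enc, [mpt], pending)
        ceiling = max(ubs.get(c, L_opt + enc.n_characters) for c in pending)
        counters = _exact_counter_lengths(enc, L_opt, pending, ceiling)
        for clade, (length, tree) in zip(pending, counters):
            if length is None:  # pragma: no cover
                raise RuntimeError("counter search ceiling too low")
            counter_len[clade] = length
            counter_tree[clade] = tree
    elif pending:
        found = _tree_set_counters(
            enc, search_result.optimal_trees, pending, L_opt, margin
        )
        for clade in pending:
            if clade not in found:
                raise RuntimeError(
                    f"no counter-tree within margin {margin} for {sorted(clade)}; "
                    "increase the margin"
                )
            counter_len[clade], counter_tree[clade] = found[clade]

    records = []
    for clade in clades:
        absolute = counter_len[clade] - L_opt
        relative = _relative_from_trees(enc, mpt, counter_tree[clade])
        records.append(
            SupportRecord(
                clade=clade, absolute_bremer=absolute, relative_bremer=relative
            )
        )
    return records
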