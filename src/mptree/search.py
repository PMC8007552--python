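"""Most-parsimonious-tree search: heuristic, branch-and-bound and exhaustive.

The exact searches use implicit enumeration by stepwise addition: the most
conflicting unplaced taxon is inserted into every branch of the growing
tree, and a partial tree is abandoned as soon as an admissible lower bound
on any completion exceeds the best length known (the compiled kernel in
``_bbcore`` documents the bound).  Insertion costs are exact and cheap:
rooting the enlarged tree at the new leaf shows that attaching leaf ``x``
to branch ``e`` raises the Fitch length by one step for exactly the
characters in which ``x``'s state set is disjoint from the branch state
set (the Fitch combination of the two directional state sets meeting at
``e``), so a whole level of candidate insertions costs one down-pass, one
up-pass and one AND per branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._bbcore import bb_core
from .engine import EncodedMatrix, fitch_combine, tree_length
from .trees import TreeTopology

__all__ = [
    "SearchConfig",
    "SearchResult",
    "heuristic_search",
    "branch_and_bound",
    "exhaustive_search",
    "strict_consensus",
]

logger = logging.getLogger(__name__)

_STRATEGIES = ("heuristic", "branch_and_bound", "exhaustive")


@dataclass(frozen=True)
class SearchConfig:
    """Settings for tree search.

    ``seed`` fixes every stochastic choice (replicate addition orders);
    ``suboptimal_margin`` additionally retains trees within that many steps
    of the optimum (used by Bremer support).
    """

    strategy: str = "branch_and_bound"
    n_replicates: int = 10
    swap: str = "tbr"
    seed: int = 0
    suboptimal_margin: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.swap not in ("spr", "tbr"):
            raise ValueError(f"unknown swap {self.swap!r}")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a tree search.

    ``optimal_trees`` hold distinct unrooted binary topologies of length
    ``best_length``; ``proven_optimal`` is True only for exact strategies.
    ``suboptimal_trees`` maps retained near-optimal topologies to their
    lengths when a positive margin was requested.
    """

    best_length: int
    optimal_trees: Tuple[TreeTopology, ...]
    proven_optimal: bool
    search_log: Tuple[str, ...] = ()
    suboptimal_trees: Tuple[Tuple[int, TreeTopology], ...] = ()


class TrivialInstanceError(ValueError):
    """Search requested on fewer than four taxa."""


# ---------------------------------------------------------------------------
# low-level stepwise-addition machinery (taxa as matrix row indices)


class _StepwiseCore:
    """Mutable rooted scaffold for stepwise addition over taxon indices.

    The tree is held rooted on the pendant branch of the first added taxon
    ``t0``: the root has children ``[t0, rest]``.  Every unrooted branch of
    the current tree corresponds to exactly one node ``c`` other than the
    root and ``t0`` (the branch between ``c`` and its parent; ``rest``
    stands for the pendant branch of ``t0`` itself).
    """

    def __init__(self, enc: EncodedMatrix):
        self.enc = enc
        self.n = enc.n_taxa
        self.packed = enc.packed
        self.lsb = enc.lane_lsb
        self.nchar = enc.n_characters
        size = 2 * self.n
        self.root = size - 1
        self.kids: List[Optional[List[int]]] = [None] * size
        self.parent = [-1] * size
        self.t0 = -1

    def start(self, t0: int, t1: int, t2: int) -> None:
        inner = self.n
        self.t0 = t0
        self.kids[self.root] = [t0, inner]
        self.kids[inner] = [t1, t2]
        self.parent[t0] = self.root
        self.parent[inner] = self.root
        self.parent[t1] = inner
        self.parent[t2] = inner

    def insert(self, node: int, leaf: int, new_internal: int) -> None:
        """Attach ``leaf`` to the branch above ``node`` via ``new_internal``."""
        p = self.parent[node]
        self.kids[new_internal] = [node, leaf]
        self.parent[new_internal] = p
        self.parent[node] = new_internal
        self.parent[leaf] = new_internal
        ks = self.kids[p]
        ks[ks.index(node)] = new_internal

    def remove(self, node: int, leaf: int, new_internal: int) -> None:
        p = self.parent[new_internal]
        ks = self.kids[p]
        ks[ks.index(new_internal)] = node
        self.parent[node] = p
        self.kids[new_internal] = None

    def _nodes_below(self, node: int, out: List[int]) -> None:
        out.append(node)
        ks = self.kids[node]
        if ks is not None:
            for k in ks:
                self._nodes_below(k, out)

    def branch_nodes(self) -> List[int]:
        """One node per insertable unrooted branch (everything but root, t0)."""
        out: List[int] = []
        self._nodes_below(self.kids[self.root][1], out)
        return out

    def down_up(self) -> Tuple[Dict[int, int], Dict[int, int], int]:
        """Directional Fitch state sets and current partial length.

        Returns ``(down, up, length)`` where ``down[v]`` is the Fitch set of
        the subtree below ``v`` and ``up[v]`` the set of the rest of the tree
        seen from ``v``'s parent side.
        """
        down: Dict[int, int] = {}
        up: Dict[int, int] = {}
        lsb, nchar = self.lsb, self.nchar
        total = 0

        def dpass(v: int) -> int:
            nonlocal total
            ks = self.kids[v]
            if ks is None:
                d = self.packed[v]
            else:
                a = dpass(ks[0])
                b = dpass(ks[1])
                d, steps = fitch_combine(a, b, lsb, nchar)
                total += steps
            down[v] = d
            return d

        rest = self.kids[self.root][1]
        dpass(self.t0)
        dpass(rest)
        # length of the whole partial tree includes the join at the root
        _, root_steps = fitch_combine(down[self.t0], down[rest], lsb, nchar)
        total += root_steps

        up[rest] = down[self.t0]

        def upass(v: int) -> None:
            ks = self.kids[v]
            if ks is None:
                return
            a, b = ks
            up[a], _ = fitch_combine(up[v], down[b], lsb, nchar)
            up[b], _ = fitch_combine(up[v], down[a], lsb, nchar)
            upass(a)
            upass(b)

        upass(rest)
        return down, up, total

    def insertion_costs(self, leaf_row: int) -> Tuple[int, List[Tuple[int, int]]]:
        """Exact Fitch length increase of attaching ``leaf_row`` to each branch.

        Returns ``(partial_length, [(cost, branch_node), ...])``.
        """
        down, up, length = self.down_up()
        lsb, nchar = self.lsb, self.nchar
        out: List[Tuple[int, int]] = []
        for c in self.branch_nodes():
            edge_set, _ = fitch_combine(down[c], up[c], lsb, nchar)
            inter = edge_set & leaf_row
            inter |= inter >> 4
            inter |= inter >> 2
            inter |= inter >> 1
            cost = nchar - (inter & lsb).bit_count()
            out.append((cost, c))
        return length, out

    def topology(self) -> TreeTopology:
        labels = self.enc.taxa

        def shape(v: int):
            ks = self.kids[v]
            if ks is None:
                return labels[v]
            return (shape(ks[0]), shape(ks[1]))

        rest = self.kids[self.root][1]
        return TreeTopology((labels[self.t0], shape(rest)), rooted=False)

    def subtree_leafsets(self) -> List[FrozenSet[int]]:
        """Leaf-index sets below every non-root internal node."""
        out: List[FrozenSet[int]] = []

        def walk(v: int) -> FrozenSet[int]:
            ks = self.kids[v]
            if ks is None:
                return frozenset([v])
            s = walk(ks[0]) | walk(ks[1])
            out.append(s)
            return s

        walk(self.kids[self.root][1])
        return out


def _singleton_state_masks(enc: EncodedMatrix) -> np.ndarray:
    """(n_taxa, n_char) uint8: the state bit for unambiguously scored cells,
    zero for ambiguous cells."""
    sets = enc.state_sets
    popcounts = np.unpackbits(sets[:, :, None], axis=2).sum(axis=2)
    return np.where(popcounts == 1, sets, 0).astype(np.uint8)


def _best_triple(enc: EncodedMatrix) -> Tuple[int, int, int]:
    """The three mutually most conflicting taxa, to seed implicit
    enumeration with as much length as possible."""
    n = enc.n_taxa
    lsb, nchar = enc.lane_lsb, enc.n_characters
    best_trip, best_len = (0, 1, 2), -1
    for i in range(n):
        for j in range(i + 1, n):
            ab, s1 = fitch_combine(enc.packed[i], enc.packed[j], lsb, nchar)
            for k in range(j + 1, n):
                _, s2 = fitch_combine(ab, enc.packed[k], lsb, nchar)
                if s1 + s2 > best_len:
                    best_len, best_trip = s1 + s2, (i, j, k)
    return best_trip


def _unpack_packed(value: int, nchar: int) -> np.ndarray:
    """Packed 16-bit-lane state sets -> (nchar,) uint16 vector."""
    return np.frombuffer(value.to_bytes(2 * nchar, "little"), dtype=np.uint16).copy()


def _enumerate(
    enc: EncodedMatrix,
    upper_bound: Optional[int],
    forbidden_clade: Optional[FrozenSet[int]] = None,
    margin: int = 0,
    prune: bool = True,
    max_trees: Optional[int] = None,
    start_order: Optional[Sequence[int]] = None,
) -> Tuple[Optional[int], Dict[TreeTopology, int], int, int]:
    """Stepwise-addition enumeration with bound pruning.

    Taxa are chosen dynamically: at every node the unplaced taxon whose
    cheapest insertion (plus the states that would still remain exclusive
    to the other unplaced taxa) is largest goes next — completeness does
    not depend on the choice, but picking the most conflicting taxon makes
    the admissible bound bite early.  Completed trees containing
    ``forbidden_clade`` as a bipartition are not candidates
    (reverse-constrained search for Bremer support).

    Returns ``(best_length, {topology: length} within margin of best,
    n_complete, n_partial_explored)``; ``best_length`` is None when nothing
    qualified under ``upper_bound``.
    """
    n = enc.n_taxa
    nchar = enc.n_characters
    core = _StepwiseCore(enc)
    triple = tuple(start_order[:3]) if start_order else _best_triple(enc)
    core.start(*triple)
    target: Optional[FrozenSet[int]] = None
    if forbidden_clade is not None:
        full = frozenset(range(n))
        target = (
            forbidden_clade
            if triple[0] not in forbidden_clade
            else full - forbidden_clade
        )

    single = _singleton_state_masks(enc)  # (n, C) uint8
    bits = np.unpackbits(single[:, :, None], axis=2, bitorder="little")  # (n, C, 8)
    rows16 = enc.state_sets.astype(np.uint16)  # (n, C)
    placed_bits = bits[list(triple)].sum(axis=0).astype(np.int16)  # (C, 8) counts
    unplaced = [t for t in range(n) if t not in triple]
    counts = bits[unplaced].sum(axis=0).astype(np.int16) if unplaced else np.zeros(
        (nchar, 8), np.int16
    )

    best: Optional[int] = None
    ceiling = upper_bound  # prune strictly above this
    found: Dict[TreeTopology, int] = {}
    n_complete = 0
    n_partial = 0

    def record(length: int) -> None:
        nonlocal best, ceiling, n_complete
        n_complete += 1
        if target is not None and target in core.subtree_leafsets():
            return
        if best is None or length < best:
            best = length
            if prune:
                ceiling = best + margin
            for t, l in list(found.items()):
                if l > best + margin:
                    del found[t]
        if length <= best + margin:
            if max_trees is None or len(found) < max_trees:
                found[core.topology()] = length

    def future_bounds() -> Tuple[np.ndarray, int]:
        """Per-unplaced-taxon residual state requirements.

        ``t2[i]``: once unplaced taxon ``i`` is attached, how many character
        states would still be exclusive to the remaining unplaced taxa
        (each must arise at least once); also returns the same quantity for
        the full unplaced set.
        """
        placed_empty = placed_bits.sum(axis=1, keepdims=True) == 0  # (C, 1)
        avail = (counts > 0) & (placed_bits == 0)
        per_char = avail.sum(axis=1)
        extra_all = int(per_char.sum() - (placed_empty[:, 0] & (per_char > 0)).sum())
        u_bits = bits[unplaced]  # (U, C, 8)
        rest = counts[None, :, :] - u_bits
        avail2 = (rest > 0) & (placed_bits[None] == 0) & (u_bits == 0)
        per_char2 = avail2.sum(axis=2)  # (U, C)
        empty2 = placed_empty.T & (u_bits.sum(axis=2) == 0) & (per_char2 > 0)
        t2 = per_char2.sum(axis=1) - empty2.sum(axis=1)
        return t2.astype(np.int64), extra_all

    def step(k: int) -> None:
        nonlocal n_partial
        n_partial += 1
        down, up, length = core.down_up()
        if not unplaced:
            record(length)
            return
        branch = core.branch_nodes()
        edge_sets = np.empty((len(branch), nchar), dtype=np.uint16)
        for i, c in enumerate(branch):
            es, _ = fitch_combine(down[c], up[c], core.lsb, nchar)
            edge_sets[i] = _unpack_packed(es, nchar)
        urows = rows16[unplaced]  # (U, C)
        disjoint = (urows[:, None, :] & edge_sets[None, :, :]) == 0
        costm = disjoint.sum(axis=2)  # (U, E)
        min_ins = costm.min(axis=1)
        if prune and ceiling is not None:
            t2, extra_all = future_bounds()
            scores = min_ins + t2
            bound = length + max(extra_all, int(scores.max()))
            if bound > ceiling:
                return
            pick_pos = int(np.argmax(scores))
        else:
            t2 = np.zeros(len(unplaced), dtype=np.int64)
            pick_pos = 0
        leaf = unplaced[pick_pos]
        leaf_t2 = int(t2[pick_pos])
        edge_order = np.argsort(costm[pick_pos], kind="stable")
        new_internal = n + k - 2

        # place `leaf`
        unplaced.pop(pick_pos)
        counts_delta = bits[leaf].astype(np.int16)
        counts[:] = counts - counts_delta
        placed_bits[:] = placed_bits + counts_delta
        for i in edge_order:
            cost = int(costm[pick_pos, i])
            if (
                prune
                and ceiling is not None
                and length + cost + leaf_t2 > ceiling
            ):
                continue
            node = branch[int(i)]
            core.insert(node, leaf, new_internal)
            step(k + 1)
            core.remove(node, leaf, new_internal)
        counts[:] = counts + counts_delta
        placed_bits[:] = placed_bits - counts_delta
        unplaced.insert(pick_pos, leaf)

    step(3)
    return best, found, n_complete, n_partial


_BIG = 1 << 60


def _clade_mask(clade: FrozenSet[int], t0: int, n: int) -> int:
    """uint64 leaf bitmask of the bipartition side not containing ``t0``."""
    side = clade if t0 not in clade else frozenset(range(n)) - clade
    mask = 0
    for t in side:
        mask |= 1 << t
    return mask


def _kids_topology(kids_row: np.ndarray, enc: EncodedMatrix, t0: int) -> TreeTopology:
    """Rebuild an unrooted topology from a kernel child-array snapshot."""
    labels = enc.taxa
    n = enc.n_taxa
    root = 2 * n - 1

    def shape(v: int):
        if kids_row[v, 0] < 0:
            return labels[v]
        return (shape(int(kids_row[v, 0])), shape(int(kids_row[v, 1])))

    return TreeTopology((labels[t0], shape(int(kids_row[root, 1]))), rooted=False)


def _pattern_compress(enc: EncodedMatrix) -> Tuple[np.ndarray, np.ndarray, int]:
    """Collapse columns for the kernel: unique informative patterns with
    multiplicities, plus the constant length contributed by uninformative
    columns (whose steps are the same on every binary tree, namely their
    number of observed states minus one)."""
    offset = 0
    patterns: Dict[bytes, int] = {}
    cols: List[np.ndarray] = []
    weights: List[int] = []
    for c in range(enc.n_characters):
        col = enc.state_sets[:, c]
        if not enc.informative[c]:
            mask = int(enc.observed_masks[c])
            offset += max(0, mask.bit_count() - 1)
            continue
        key = col.tobytes()
        if key in patterns:
            weights[patterns[key]] += 1
        else:
            patterns[key] = len(cols)
            cols.append(col)
            weights.append(1)
    if cols:
        rows = np.ascontiguousarray(np.stack(cols, axis=1))
    else:
        rows = np.zeros((enc.n_taxa, 0), dtype=np.uint8)
    return rows, np.asarray(weights, dtype=np.int64), offset


def _run_core(
    enc: EncodedMatrix,
    ceiling: int,
    best0: int = _BIG,
    margin: int = 0,
    clades: Sequence[FrozenSet[int]] = (),
    store_cap: int = 0,
    fast_u: int = 11,
    fixed_order: Optional[Sequence[int]] = None,
) -> Dict[str, object]:
    """Drive the compiled enumeration kernel and decode its results."""
    if enc.n_taxa > 64:
        raise ValueError("exact search supports at most 64 taxa")
    triple = _best_triple(enc)
    t0 = triple[0]
    masks = np.array(
        [_clade_mask(c, t0, enc.n_taxa) for c in clades], dtype=np.uint64
    )
    rows, weights, offset = _pattern_compress(enc)
    n, C = rows.shape
    W = max(1, (C + 7) // 8)
    padded = np.full((n, W * 8), 0xFF, dtype=np.uint8)  # pad lanes never step
    padded[:, :C] = rows
    rows64 = np.ascontiguousarray(padded).view(np.uint64).reshape(n, W)
    wlane = np.zeros(W * 8, dtype=np.int64)
    wlane[:C] = weights
    idx = np.arange(256)
    bits = (idx[:, None] >> np.arange(8)[None, :]) & 1  # (256, 8)
    wtab = np.ascontiguousarray((bits @ wlane.reshape(W, 8).T).T).astype(np.int64)
    cap = store_cap
    while True:
        (
            best,
            n_complete,
            n_partial,
            counter_best,
            counter_kids,
            stored_kids,
            stored_len,
            n_stored,
            overflow,
        ) = bb_core(
            rows,
            weights,
            rows64,
            wlane,
            wtab,
            triple[0],
            triple[1],
            triple[2],
            np.int64(ceiling - offset),
            np.int64(best0 - offset if best0 < _BIG else _BIG),
            np.int64(margin),
            masks,
            cap,
            fast_u,
            np.asarray(
                fixed_order if fixed_order is not None else [], dtype=np.int32
            ),
        )
        if not overflow:
            break
        cap *= 4  # pragma: no cover - generous caps, retried defensively
    found: Dict[TreeTopology, int] = {}
    if store_cap > 0:
        for i in range(int(n_stored)):
            l = int(stored_len[i])
            if best < _BIG and l <= int(best) + margin:
                found[_kids_topology(stored_kids[i], enc, t0)] = l + offset
    counters = []
    for q in range(len(masks)):
        if counter_best[q] < _BIG:
            counters.append(
                (
                    int(counter_best[q]) + offset,
                    _kids_topology(counter_kids[q], enc, t0),
                )
            )
        else:
            counters.append((None, None))
    return {
        "best": None if best >= _BIG else int(best) + offset,
        "found": found,
        "counters": counters,
        "n_complete": int(n_complete),
        "n_partial": int(n_partial),
    }


def _verify(result_trees: Iterable[TreeTopology], enc: EncodedMatrix, L: int) -> None:
    for t in result_trees:
        got = tree_length(t, enc)
        if got != L:  # pragma: no cover - internal consistency guard
            raise AssertionError(f"search returned a tree of length {got}, not {L}")


# ---------------------------------------------------------------------------
# adjacency-based branch swapping for the heuristic search


def _adj_length(adj: Dict[int, List[int]], enc: EncodedMatrix) -> int:
    lsb, nchar = enc.lane_lsb, enc.n_characters
    packed = enc.packed
    root = min(v for v in adj if v < enc.n_taxa)
    total = 0

    def walk(v: int, parent: int) -> int:
        nonlocal total
        nbrs = [w for w in adj[v] if w != parent]
        if not nbrs:
            return packed[v]
        acc = walk(nbrs[0], v)
        for w in nbrs[1:]:
            acc, steps = fitch_combine(acc, walk(w, v), lsb, nchar)
            total += steps
        return acc

    start = adj[root][0]
    acc = walk(start, root)
    _, steps = fitch_combine(acc, packed[root], lsb, nchar)
    total += steps
    return total


def _adj_topology(adj: Dict[int, List[int]], enc: EncodedMatrix) -> TreeTopology:
    labels = enc.taxa
    anchor = min(v for v in adj if v < enc.n_taxa)

    def shape(v: int, parent: int):
        nbrs = [w for w in adj[v] if w != parent]
        if not nbrs:
            return labels[v]
        kids = tuple(shape(w, v) for w in nbrs)
        return kids if len(kids) > 1 else kids[0]

    return TreeTopology((labels[anchor], shape(adj[anchor][0], anchor)), rooted=False)


def _component_edges(
    adj: Dict[int, List[int]], start: int, blocked: int
) -> List[Tuple[int, int]]:
    """Undirected edges of the component containing ``start`` when the edge
    to ``blocked`` is severed."""
    seen = {start}
    stack = [start]
    edges = []
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if v == start and w == blocked:
                continue
            if w not in seen:
                seen.add(w)
                edges.append((v, w) if v < w else (w, v))
                stack.append(w)
    return sorted(set(edges))


def _spr_moves(adj: Dict[int, List[int]]) -> List[Tuple[int, int, Tuple[int, int]]]:
    """(pruned_root, suppressed_node, regraft_edge) triples."""
    moves = []
    for p in sorted(adj):
        if len(adj[p]) != 3:
            continue
        for v in sorted(adj[p]):
            a, b = [w for w in adj[p] if w != v]
            for edge in _component_edges(adj, a, p) + _component_edges(adj, b, p):
                if p in edge:
                    continue
                moves.append((v, p, edge))
    return moves


def _apply_spr(
    adj: Dict[int, List[int]], v: int, p: int, edge: Tuple[int, int]
) -> Dict[int, List[int]]:
    new = {k: list(ws) for k, ws in adj.items()}
    a, b = [w for w in new[p] if w != v]
    new[a].remove(p)
    new[b].remove(p)
    new[a].append(b)
    new[b].append(a)
    x, y = edge
    new[x].remove(y)
    new[y].remove(x)
    new[x].append(p)
    new[y].append(p)
    new[p] = [x, y, v]
    return new


def _tbr_extra_moves(
    adj: Dict[int, List[int]]
) -> List[Tuple[int, int, Tuple[int, int], Tuple[int, int]]]:
    """Bisections of internal edges with reattachment points on both sides."""
    moves = []
    internal = [v for v in sorted(adj) if len(adj[v]) == 3]
    for u in internal:
        for v in sorted(adj[u]):
            if v < u or len(adj[v]) != 3:
                continue

            def attach_points(node: int, other: int) -> List[Tuple[int, int]]:
                # edges of the component after `node` is suppressed: drop the
                # two edges incident to `node`, add the merged edge they form
                edges = [e for e in _component_edges(adj, node, other) if node not in e]
                a, b = [w for w in adj[node] if w != other]
                merged = (a, b) if a < b else (b, a)
                return edges + [merged]

            side_u = attach_points(u, v)
            side_v = attach_points(v, u)
            for eu in side_u:
                for ev in side_v:
                    if eu == side_u[-1] and ev == side_v[-1]:
                        continue  # both at their original edges: identity
                    moves.append((u, v, eu, ev))
    return moves


def _apply_tbr(
    adj: Dict[int, List[int]],
    u: int,
    v: int,
    eu: Tuple[int, int],
    ev: Tuple[int, int],
) -> Dict[int, List[int]]:
    new = {k: list(ws) for k, ws in adj.items()}
    new[u].remove(v)
    new[v].remove(u)
    for node, edge in ((u, eu), (v, ev)):
        a, b = new[node]
        new[a].remove(node)
        new[b].remove(node)
        new[a].append(b)
        new[b].append(a)
        x, y = edge
        new[x].remove(y)
        new[y].remove(x)
        new[x].append(node)
        new[y].append(node)
        new[node] = [x, y]
    new[u].append(v)
    new[v].append(u)
    return new


def _swap_to_optimum(
    adj: Dict[int, List[int]], enc: EncodedMatrix, swap: str
) -> Tuple[Dict[int, List[int]], int]:
    """First-improvement branch swapping to a local optimum."""
    length = _adj_length(adj, enc)
    improved = True
    while improved:
        improved = False
        for move in _spr_moves(adj):
            cand = _apply_spr(adj, *move)
            l = _adj_length(cand, enc)
            if l < length:
                adj, length, improved = cand, l, True
                break
        if improved:
            continue
        if swap == "tbr":
            for move in _tbr_extra_moves(adj):
                cand = _apply_tbr(adj, *move)
                l = _adj_length(cand, enc)
                if l < length:
                    adj, length, improved = cand, l, True
                    break
    return adj, length


def _wagner_build(enc: EncodedMatrix, order: Sequence[int]) -> Dict[int, List[int]]:
    """Greedy stepwise addition: each taxon goes to its cheapest branch."""
    n = enc.n_taxa
    core = _StepwiseCore(enc)
    core.start(order[0], order[1], order[2])
    for k in range(3, n):
        _, costs = core.insertion_costs(enc.packed[order[k]])
        _, node = min(costs, key=lambda x: (x[0], x[1]))
        core.insert(node, order[k], n + k - 2)
    adj: Dict[int, List[int]] = {}

    def add_edge(a: int, b: int) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def walk(v: int, parent: int) -> None:
        ks = core.kids[v]
        if ks is None:
            return
        for k in ks:
            add_edge(v, k)
            walk(k, v)

    rest = core.kids[core.root][1]
    walk(rest, core.root)
    # splice the root out: t0 joins the top of `rest`
    add_edge(core.t0, rest)
    return adj


# ---------------------------------------------------------------------------
# public search strategies


def _require_searchable(enc: EncodedMatrix) -> None:
    if enc.n_taxa < 4:
        raise TrivialInstanceError(
            f"search needs >= 4 taxa, got {enc.n_taxa}; "
            "fewer taxa admit a single unrooted topology"
        )


def heuristic_search(enc: EncodedMatrix, config: SearchConfig = SearchConfig("heuristic")) -> SearchResult:
    """Random-addition-sequence Wagner builds followed by branch swapping.

    Deterministic given ``config.seed``.  The best length found is an upper
    bound on the optimum; ``proven_optimal`` is always False.
    """
    _require_searchable(enc)
    rng = np.random.default_rng(config.seed)
    n = enc.n_taxa
    best_len: Optional[int] = None
    best_trees: Dict[TreeTopology, None] = {}
    log = []
    for rep in range(config.n_replicates):
        order = list(rng.permutation(n))
        adj = _wagner_build(enc, order)
        adj, length = _swap_to_optimum(adj, enc, config.swap)
        topo = _adj_topology(adj, enc)
        if best_len is None or length < best_len:
            best_len = length
            best_trees = {topo: None}
        elif length == best_len:
            best_trees[topo] = None
        log.append(f"replicate {rep}: local optimum {length}")
        logger.debug("heuristic replicate %d: length %d", rep, length)
    _verify(best_trees, enc, best_len)
    return SearchResult(
        best_length=best_len,
        optimal_trees=tuple(best_trees),
        proven_optimal=False,
        search_log=tuple(log),
    )


def branch_and_bound(
    enc: EncodedMatrix,
    initial_upper_bound: Optional[int] = None,
    config: Optional[SearchConfig] = None,
) -> SearchResult:
    """Exact search by implicit enumeration; returns all optimal topologies.

    When no ``initial_upper_bound`` is supplied a short heuristic search
    provides one.  A positive ``config.suboptimal_margin`` additionally
    collects every topology within that many steps of the optimum.
    """
    _require_searchable(enc)
    config = config or SearchConfig()
    margin = max(0, config.suboptimal_margin)
    if initial_upper_bound is None:
        heur = heuristic_search(
            enc,
            SearchConfig(
                "heuristic",
                n_replicates=max(2, min(5, config.n_replicates)),
                swap=config.swap,
                seed=config.seed,
            ),
        )
        initial_upper_bound = heur.best_length
    res = _run_core(
        enc,
        ceiling=initial_upper_bound + margin,
        margin=margin,
        store_cap=100_000,
    )
    best = res["best"]
    if best is None:  # pragma: no cover - upper bound always attainable
        raise RuntimeError("branch-and-bound found no tree under its bound")
    found = res["found"]
    optimal = tuple(t for t, l in found.items() if l == best)
    subopt = tuple((l, t) for t, l in found.items() if l > best)
    _verify(optimal, enc, best)
    log = (
        f"initial upper bound: {initial_upper_bound}",
        f"partial trees explored: {res['n_partial']}",
        f"complete trees scored: {res['n_complete']}",
    )
    return SearchResult(
        best_length=best,
        optimal_trees=optimal,
        proven_optimal=True,
        search_log=log,
        suboptimal_trees=subopt,
    )


def exhaustive_search(enc: EncodedMatrix) -> SearchResult:
    """Score every unrooted binary topology (allowed up to nine taxa)."""
    _require_searchable(enc)
    if enc.n_taxa > 9:
        raise ValueError(
            f"exhaustive search over {enc.n_taxa} taxa would enumerate too "
            "many topologies; use branch_and_bound"
        )
    best, found, n_complete, _ = _enumerate(
        enc, None, prune=False, start_order=list(range(enc.n_taxa))
    )
    optimal = tuple(t for t, l in found.items() if l == best)
    _verify(optimal, enc, best)
    return SearchResult(
        best_length=best,
        optimal_trees=optimal,
        proven_optimal=True,
        search_log=(f"topologies scored: {n_complete}",),
    )


def strict_consensus(trees: Sequence[TreeTopology]) -> TreeTopology:
    """Strict consensus: keep exactly the bipartitions shared by all trees."""
    if not trees:
        raise ValueError("strict consensus needs at least one tree")
    leafsets = {t.leaves for t in trees}
    if len(leafsets) != 1:
        raise ValueError("strict consensus requires identical leaf sets")
    if len(trees) == 1:
        return trees[0].unroot()
    common = set.intersection(*(t.bipartitions() for t in trees))
    leaves = trees[0].leaves
    anchor = min(leaves)
    rest = sorted(leaves - {anchor})

    def build(elems: FrozenSet[str], clusters: List[FrozenSet[str]]):
        tops = [
            c
            for c in clusters
            if c < elems and not any(c < d < elems for d in clusters)
        ]
        used: Set[str] = set()
        kids = []
        for c in sorted(tops, key=lambda s: (len(s), sorted(s))):
            inner = [d for d in clusters if d < c]
            kids.append(build(c, inner))
            used |= c
        for e in sorted(elems - used):
            kids.append(e)
        return tuple(kids) if len(kids) > 1 else kids[0]

    clusters = sorted(common, key=len)
    top = build(frozenset(rest), [c for c in clusters])
    if isinstance(top, str):
        top = (top,)
    return TreeTopology((anchor, top), rooted=False)
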