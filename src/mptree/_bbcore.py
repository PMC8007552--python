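"""Compiled branch-and-bound kernel for implicit enumeration.

Exact parsimony search by stepwise addition over taxon indices.  State
sets are uint8 bit masks (states 0-7).  The caller collapses identical
columns to weighted patterns and strips parsimony-uninformative columns
(whose steps are the same constant on every binary tree), so the kernel
only sees the topology-dependent part of the length.

Two regimes:

* While many taxa remain unplaced, every node recomputes directional
  Fitch sets and an admissible "chain" bound: repeatedly take the
  unplaced taxon whose cheapest insertion is most expensive, where a
  taxon's cost is the minimum over branches of the summed weight of
  characters in which its states are disjoint from both the branch
  state-set union and the states of taxa chained before it.  Earlier
  chain members can only add their own states to any branch of the grown
  tree, so each term lower-bounds that taxon's true attachment cost in
  any completion.

* Once few taxa remain (``fast_u``), the subtree is enumerated by a fast
  tail working on 8-bit lanes packed into uint64 words: each node runs
  one packed down/up pass, scores every insertion of the next taxon in a
  few word operations per branch, and handles the last taxon entirely at
  its parent.  The switch node's chain terms double as precomputed suffix
  bounds (their admissibility argument survives every insertion made
  below the switch).

The kernel also tracks, for a list of leaf subsets (uint64 leaf
bitmasks), the shortest completed tree that does *not* show the subset as
a bipartition — the reverse-constrained quantity behind Bremer support.

Limited to 64 taxa; characters (patterns) unlimited.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = np.int64(1) << np.int64(60)

_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_M2 = np.uint64(0x3333333333333333)
_M1 = np.uint64(0x5555555555555555)
_L1 = np.uint64(0x0101010101010101)
_FF = np.uint64(0xFF)
_GATHER = np.uint64(0x0102040810204080)  # bits 8k -> byte 56..63
_U1 = np.uint64(1)
_U0 = np.uint64(0)


@njit(cache=True)
def _zero_lanes(x: np.uint64) -> np.uint64:
    """Bit 0 of each 8-bit lane set iff that lane of ``x`` is zero."""
    y = x
    y |= (y >> np.uint64(4)) & _M4
    y |= (y >> np.uint64(2)) & _M2
    y |= (y >> np.uint64(1)) & _M1
    return (~y) & _L1


@njit(cache=True)
def bb_core(
    rows: np.ndarray,  # (n, C) uint8 state sets (ambiguous = observed mask)
    weights: np.ndarray,  # (C,) int64 pattern weights
    rows64: np.ndarray,  # (n, W) uint64 lane-packed rows, 0xFF padding
    wlane: np.ndarray,  # (W*8,) int64 per-lane weights (0 on padding)
    wtab: np.ndarray,  # (W, 256) int64 summed weights per lane-bit pattern
    t0: int,
    t1: int,
    t2: int,
    ceiling0: np.int64,
    best0: np.int64,
    margin: np.int64,
    clade_masks: np.ndarray,  # (K,) uint64, side not containing t0
    store_cap: int,
    fast_u: int,
    fixed_order: np.ndarray,  # (n,) int32 global addition order, or empty
):
    n, C = rows.shape
    W = rows64.shape[1]
    size = 2 * n
    root = size - 1

    kids = np.full((size, 2), -1, np.int32)
    parent = np.full(size, -1, np.int32)
    down = np.zeros((size, C), np.uint8)
    up = np.zeros((size, C), np.uint8)
    postord = np.empty(size, np.int32)
    stack = np.empty(size, np.int32)
    edge_union = np.zeros((size, C), np.uint8)
    edge_set = np.zeros((size, C), np.uint8)
    acc = np.zeros(C, np.uint8)
    node_mask = np.zeros(size, np.uint64)

    edges_buf = np.empty((n + 1, size), np.int32)
    costs_buf = np.empty((n + 1, size), np.int64)
    cnt = np.zeros(n + 1, np.int32)
    ptr = np.zeros(n + 1, np.int32)
    lvl_leaf = np.full(n + 1, -1, np.int32)
    lvl_len = np.zeros(n + 1, np.int64)
    lvl_tail = np.zeros(n + 1, np.int64)
    placed = np.zeros(n, np.bool_)

    chain_left = np.empty(n, np.int32)
    forder = np.empty(n, np.int32)
    fterm = np.empty(n + 1, np.int64)

    # fast-tail state
    down64 = np.zeros((size, W), np.uint64)
    up64 = np.zeros((size, W), np.uint64)
    fextra = np.empty(n + 2, np.int64)
    tpost = np.empty(size, np.int32)
    tcand = np.empty((n + 1, size), np.int32)
    tcost = np.empty((n + 1, size), np.int64)
    tcnt = np.zeros(n + 1, np.int32)
    tptr = np.zeros(n + 1, np.int32)
    tlen = np.zeros(n + 1, np.int64)

    K = clade_masks.shape[0]
    counter_best = np.full(K, BIG, np.int64)
    counter_kids = np.full((K, size, 2), -1, np.int32)
    cap = store_cap if store_cap > 0 else 1
    stored_kids = np.full((cap, size, 2), -1, np.int32)
    stored_len = np.zeros(cap, np.int64)
    # mutable scalars shared with the closures:
    # 0 best, 1 ceiling, 2 n_complete, 3 n_partial, 4 n_stored, 5 overflow
    state = np.zeros(6, np.int64)
    state[0] = best0
    state[1] = ceiling0 if ceiling0 < best0 + margin else best0 + margin

    # initial three-taxon tree: root(t0, inner(t1, t2))
    inner0 = n
    kids[root, 0] = t0
    kids[root, 1] = inner0
    parent[t0] = root
    parent[inner0] = root
    kids[inner0, 0] = t1
    kids[inner0, 1] = t2
    parent[t1] = inner0
    parent[t2] = inner0
    placed[t0] = True
    placed[t1] = True
    placed[t2] = True

    def _complete(length):
        """Record a finished tree: Bremer counters, best, optional storage."""
        state[2] += 1
        rest = kids[root, 1]
        sp = 0
        stack[sp] = rest
        sp += 1
        m = 0
        while sp > 0:
            sp -= 1
            v = stack[sp]
            postord[m] = v
            m += 1
            if kids[v, 0] >= 0:
                stack[sp] = kids[v, 0]
                sp += 1
                stack[sp] = kids[v, 1]
                sp += 1
        if K > 0:
            for i in range(m - 1, -1, -1):
                v = postord[i]
                a = kids[v, 0]
                if a < 0:
                    node_mask[v] = _U1 << np.uint64(v)
                else:
                    node_mask[v] = node_mask[a] | node_mask[kids[v, 1]]
            for q in range(K):
                present = False
                for i in range(m):
                    if node_mask[postord[i]] == clade_masks[q]:
                        present = True
                        break
                if not present and length < counter_best[q]:
                    counter_best[q] = length
                    for v in range(size):
                        counter_kids[q, v, 0] = kids[v, 0]
                        counter_kids[q, v, 1] = kids[v, 1]
        if length < state[0]:
            state[0] = length
            if state[0] + margin < state[1]:
                state[1] = state[0] + margin
        if store_cap > 0 and length <= state[0] + margin:
            if state[4] < store_cap:
                stored_len[state[4]] = length
                for v in range(size):
                    stored_kids[state[4], v, 0] = kids[v, 0]
                    stored_kids[state[4], v, 1] = kids[v, 1]
                state[4] += 1
            else:
                state[5] = 1

    def _tail_eval(j, k0, nu, length):
        """Prepare (or finish) level ``j``: score all insertions of
        ``forder[j]`` against the current tree's branch state sets.
        Returns 1 when candidates are staged, 0 when the level is a
        completion layer or fully pruned."""
        x_leaf = forder[j]
        # rebuild the traversal order of the current tree
        sp2 = 0
        stack[sp2] = kids[root, 1]
        sp2 += 1
        mm = 0
        while sp2 > 0:
            sp2 -= 1
            v = stack[sp2]
            tpost[mm] = v
            mm += 1
            if kids[v, 0] >= 0:
                stack[sp2] = kids[v, 0]
                sp2 += 1
                stack[sp2] = kids[v, 1]
                sp2 += 1
        # packed down-pass (no step counting: length is already known)
        for i in range(mm - 1, -1, -1):
            v = tpost[i]
            a = kids[v, 0]
            if a < 0:
                for w_ in range(W):
                    down64[v, w_] = rows64[v, w_]
            else:
                b = kids[v, 1]
                for w_ in range(W):
                    x = down64[a, w_] & down64[b, w_]
                    z = _zero_lanes(x)
                    if z != _U0:
                        full = z * _FF
                        down64[v, w_] = (
                            (down64[a, w_] | down64[b, w_]) & full
                        ) | (x & ~full)
                    else:
                        down64[v, w_] = x
        # packed up-pass
        rest2 = kids[root, 1]
        for w_ in range(W):
            up64[rest2, w_] = rows64[t0, w_]
        for i in range(mm):
            v = tpost[i]
            a = kids[v, 0]
            if a >= 0:
                b = kids[v, 1]
                for w_ in range(W):
                    x = up64[v, w_] & down64[b, w_]
                    z = _zero_lanes(x)
                    if z != _U0:
                        full = z * _FF
                        up64[a, w_] = (
                            (up64[v, w_] | down64[b, w_]) & full
                        ) | (x & ~full)
                    else:
                        up64[a, w_] = x
                    y = up64[v, w_] & down64[a, w_]
                    z = _zero_lanes(y)
                    if z != _U0:
                        full = z * _FF
                        up64[b, w_] = (
                            (up64[v, w_] | down64[a, w_]) & full
                        ) | (y & ~full)
                    else:
                        up64[b, w_] = y
        # insertion cost of x_leaf on every branch, via branch Fitch sets
        last = j + 1 == nu
        ceiling = state[1]
        nstage = 0
        for i in range(mm):
            v = tpost[i]
            cost = np.int64(0)
            for w_ in range(W):
                dv = down64[v, w_]
                uv = up64[v, w_]
                x = dv & uv
                z = _zero_lanes(x)
                if z != _U0:
                    full = z * _FF
                    rset = ((dv | uv) & full) | (x & ~full)
                else:
                    rset = x
                z2 = _zero_lanes(rset & rows64[x_leaf, w_])
                if z2 != _U0:
                    cost += wtab[w_, (z2 * _GATHER) >> np.uint64(56)]
            total = length + cost
            if last:
                if total <= ceiling:
                    # materialize the completed tree just for recording
                    w_int = n + k0 + j - 2
                    p = parent[v]
                    kids[w_int, 0] = v
                    kids[w_int, 1] = x_leaf
                    parent[w_int] = p
                    parent[v] = w_int
                    parent[x_leaf] = w_int
                    if kids[p, 0] == v:
                        kids[p, 0] = w_int
                    else:
                        kids[p, 1] = w_int
                    state[3] += 1
                    _complete(total)
                    if kids[p, 0] == w_int:
                        kids[p, 0] = v
                    else:
                        kids[p, 1] = v
                    parent[v] = p
                    kids[w_int, 0] = -1
                    kids[w_int, 1] = -1
                    ceiling = state[1]
            elif total + fextra[j + 1] <= ceiling:
                tcand[j, nstage] = v
                tcost[j, nstage] = cost
                nstage += 1
        if last or nstage == 0:
            return 0
        tcnt[j] = nstage
        tptr[j] = 0
        tlen[j] = length
        return 1


    def _fast_tail(k0, nu, length0):
        """Enumerate all completions below the switch node.

        Every tail node runs one lane-packed down/up pass, derives the
        Fitch state set of every branch, and scores all insertions of the
        next suffix taxon in a few word operations each.  The last taxon
        is handled entirely at its parent: a completion's length is the
        parent length plus the scored insertion cost, so the deepest and
        most numerous nodes cost a handful of operations.
        """
        # fextra[j]: admissible bound for the suffix starting at j, from the
        # switch node's chain terms (each remains valid below the switch)
        fextra[nu] = 0
        for j in range(nu - 1, -1, -1):
            fextra[j] = fextra[j + 1] + fterm[j]

        j = 0
        if _tail_eval(0, k0, nu, length0) == 0:
            return
        while j >= 0:
            advanced = False
            while tptr[j] < tcnt[j]:
                i = tptr[j]
                tptr[j] += 1
                cost = tcost[j, i]
                if tlen[j] + cost + fextra[j + 1] > state[1]:
                    continue
                v = tcand[j, i]
                x_leaf = forder[j]
                w_int = n + k0 + j - 2
                p = parent[v]
                kids[w_int, 0] = v
                kids[w_int, 1] = x_leaf
                parent[w_int] = p
                parent[v] = w_int
                parent[x_leaf] = w_int
                if kids[p, 0] == v:
                    kids[p, 0] = w_int
                else:
                    kids[p, 1] = w_int
                state[3] += 1
                if _tail_eval(j + 1, k0, nu, tlen[j] + cost) == 1:
                    j += 1
                    advanced = True
                    break
                # level below finished (completions done or pruned): undo
                if kids[p, 0] == w_int:
                    kids[p, 0] = v
                else:
                    kids[p, 1] = v
                parent[v] = p
                kids[w_int, 0] = -1
                kids[w_int, 1] = -1
            if not advanced:
                j -= 1
                if j >= 0:
                    # undo the insertion that opened the level we just left
                    w_int = n + k0 + j - 2
                    v = kids[w_int, 0]
                    p = parent[w_int]
                    if kids[p, 0] == w_int:
                        kids[p, 0] = v
                    else:
                        kids[p, 1] = v
                    parent[v] = p
                    kids[w_int, 0] = -1
                    kids[w_int, 1] = -1

    def _evaluate(k):
        """Score the current k-leaf tree; prepare insertion candidates or
        hand the subtree to the fast tail.

        Returns 1 when candidates for the next taxon are staged at level
        ``k``, else 0 (completion handled, fast tail done, or pruned).
        """
        state[3] += 1
        ceiling = state[1]
        rest = kids[root, 1]

        # preorder (parents first); reversed it is a valid postorder
        sp = 0
        stack[sp] = rest
        sp += 1
        m = 0
        while sp > 0:
            sp -= 1
            v = stack[sp]
            postord[m] = v
            m += 1
            if kids[v, 0] >= 0:
                stack[sp] = kids[v, 0]
                sp += 1
                stack[sp] = kids[v, 1]
                sp += 1

        length = np.int64(0)
        for i in range(m - 1, -1, -1):
            v = postord[i]
            a = kids[v, 0]
            if a < 0:
                for c in range(C):
                    down[v, c] = rows[v, c]
            else:
                b = kids[v, 1]
                for c in range(C):
                    x = down[a, c] & down[b, c]
                    if x == 0:
                        down[v, c] = down[a, c] | down[b, c]
                        length += weights[c]
                    else:
                        down[v, c] = x
            if length > ceiling:
                return 0
        for c in range(C):
            if down[rest, c] & rows[t0, c] == 0:
                length += weights[c]
        if length > ceiling:
            return 0

        if k == n:
            _complete(length)
            return 0

        # directional sets away from each branch
        for c in range(C):
            up[rest, c] = rows[t0, c]
        for i in range(m):
            v = postord[i]
            a = kids[v, 0]
            if a >= 0:
                b = kids[v, 1]
                for c in range(C):
                    x = up[v, c] & down[b, c]
                    up[a, c] = x if x != 0 else (up[v, c] | down[b, c])
                    y = up[v, c] & down[a, c]
                    up[b, c] = y if y != 0 else (up[v, c] | down[a, c])
        for i in range(m):
            v = postord[i]
            for c in range(C):
                edge_union[v, c] = down[v, c] | up[v, c]
                x = down[v, c] & up[v, c]
                edge_set[v, c] = x if x != 0 else edge_union[v, c]

        # greedy chain bound: repeatedly take the unplaced taxon whose
        # cheapest insertion (given states already chained) is largest.
        # With a fixed global order the forced next taxon heads the chain
        # so that its term can be replaced by its exact insertion cost.
        nu = 0
        forced = np.int32(-1)
        if fixed_order.shape[0] == n:
            for oi in range(n):
                t = fixed_order[oi]
                if not placed[t]:
                    forced = t
                    break
        for t in range(n):
            if not placed[t]:
                if t == forced:
                    chain_left[nu] = chain_left[0]
                    chain_left[0] = t
                else:
                    chain_left[nu] = t
                nu += 1
        for c in range(C):
            acc[c] = 0
        chain = np.int64(0)
        n_left = nu
        n_ordered = 0
        while n_left > 0:
            best_cost = np.int64(-1)
            best_i = 0
            scan = 1 if (n_ordered == 0 and forced >= 0) else n_left
            for ui in range(scan):
                t = chain_left[ui]
                mincost = BIG
                for i in range(m):
                    v = postord[i]
                    cost = np.int64(0)
                    for c in range(C):
                        r = rows[t, c]
                        if r & edge_union[v, c] == 0 and r & acc[c] == 0:
                            cost += weights[c]
                    if cost < mincost:
                        mincost = cost
                        if mincost == 0:
                            break
                if mincost > best_cost:
                    best_cost = mincost
                    best_i = ui
            if best_cost == 0 and n_ordered > 0:
                break  # every remaining taxon inserts for free
            t = chain_left[best_i]
            forder[n_ordered] = t
            fterm[n_ordered] = best_cost
            n_ordered += 1
            chain += best_cost
            for c in range(C):
                acc[c] |= rows[t, c]
            chain_left[best_i] = chain_left[n_left - 1]
            chain_left[n_left - 1] = t
            n_left -= 1
        for ui in range(n_left):  # remainder after early stop, zero terms
            forder[n_ordered] = chain_left[ui]
            fterm[n_ordered] = 0
            n_ordered += 1

        if length + chain > ceiling:
            return 0
        pick = forder[0]

        if nu <= fast_u:
            _fast_tail(k, nu, length)
            return 0

        # exact insertion costs of the picked taxon (Fitch branch sets)
        nc = 0
        first_union = np.int64(BIG)
        first_exact = np.int64(BIG)
        for i in range(m):
            v = postord[i]
            cost = np.int64(0)
            for c in range(C):
                if rows[pick, c] & edge_set[v, c] == 0:
                    cost += weights[c]
            edges_buf[k, nc] = v
            costs_buf[k, nc] = cost
            nc += 1
            if cost < first_exact:
                first_exact = cost
        # replace the chain's first (union-based) term by the exact cost
        for i in range(m):
            v = postord[i]
            cost = np.int64(0)
            for c in range(C):
                if rows[pick, c] & edge_union[v, c] == 0:
                    cost += weights[c]
            if cost < first_union:
                first_union = cost
                if first_union == 0:
                    break
        tail = chain - first_union
        if length + first_exact + tail > ceiling:
            return 0

        sort_idx = np.argsort(costs_buf[k, :nc], kind="mergesort")
        tmp_e = edges_buf[k, :nc].copy()
        tmp_c = costs_buf[k, :nc].copy()
        for i in range(nc):
            edges_buf[k, i] = tmp_e[sort_idx[i]]
            costs_buf[k, i] = tmp_c[sort_idx[i]]
        cnt[k] = nc
        ptr[k] = 0
        lvl_leaf[k] = pick
        lvl_len[k] = length
        lvl_tail[k] = tail
        return 1

    if _evaluate(3) == 1:
        level = 3
        while level >= 3:
            advanced = False
            while ptr[level] < cnt[level]:
                i = ptr[level]
                ptr[level] += 1
                cost = costs_buf[level, i]
                if lvl_len[level] + cost + lvl_tail[level] > state[1]:
                    continue
                node = edges_buf[level, i]
                leaf = lvl_leaf[level]
                internal = n + level - 2
                p = parent[node]
                kids[internal, 0] = node
                kids[internal, 1] = leaf
                parent[internal] = p
                parent[node] = internal
                parent[leaf] = internal
                if kids[p, 0] == node:
                    kids[p, 0] = internal
                else:
                    kids[p, 1] = internal
                placed[leaf] = True
                if _evaluate(level + 1) == 1:
                    level += 1
                    advanced = True
                    break
                # child finished (completion, fast tail or pruned): undo
                if kids[p, 0] == internal:
                    kids[p, 0] = node
                else:
                    kids[p, 1] = node
                parent[node] = p
                kids[internal, 0] = -1
                kids[internal, 1] = -1
                placed[leaf] = False
            if not advanced:
                level -= 1
                if level >= 3:
                    leaf = lvl_leaf[level]
                    internal = n + level - 2
                    node = kids[internal, 0]
                    p = parent[internal]
                    if kids[p, 0] == internal:
                        kids[p, 0] = node
                    else:
                        kids[p, 1] = node
                    parent[node] = p
                    kids[internal, 0] = -1
                    kids[internal, 1] = -1
                    placed[leaf] = False

    return (
        state[0],
        state[2],
        state[3],
        counter_best,
        counter_kids,
        stored_kids,
        stored_len,
        state[4],
        state[5],
    )
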