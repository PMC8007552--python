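"""Outgroup rooting, ACCTRAN ancestral states and synapomorphy mapping.

After the most parsimonious tree is rooted on the outgroup, each character
is optimized with a two-pass reconstruction: a Fitch-style downpass
followed by a pre-order resolution that picks a single state per internal
vertex.  Among equally parsimonious resolutions the accelerated
transformation (ACCTRAN) convention is used: a change is placed as close
to the root as possible, so reversals are favored over parallelisms.

Concretely, per character a unit-cost Sankoff table ``cost[v][s]`` (minimum
changes in the subtree of ``v`` when ``v`` is assigned state ``s``) is
filled bottom-up; the pre-order pass then assigns each vertex the state
minimizing ``cost[v][s] + [s != parent_state]`` and, on ties, prefers a
state different from the parent (accelerating the change) and finally the
lowest-numbered state, which keeps reconstructions deterministic.  At the
root, ties prefer a state compatible with the outgroup.  The total number
of changes always equals the Fitch length of the tree.

Every change is a :class:`TransformationRecord` on the branch above the
vertex where it happens.  A record is *unique* (an exclusive synapomorphy,
the black circle of a printed cladogram) when its derived state arises on
exactly one branch for that character and never reverts; otherwise it is
homoplastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

from .engine import EncodedMatrix
from .trees import TreeTopology

__all__ = [
    "AncestralAssignment",
    "TransformationRecord",
    "root_tree",
    "acctran_reconstruct",
    "list_transformations",
    "clade_synapomorphies",
]

_INF = 1 << 20


@dataclass(frozen=True)
class TransformationRecord:
    """One character-state change placed on one branch.

    ``branch`` is the leaf set of the clade below the branch; ``character``
    is 1-based.  ``unique`` marks exclusive (non-homoplastic) changes.
    """

    branch: FrozenSet[str]
    character: int
    from_state: int
    to_state: int
    unique: bool

    @property
    def uniqueness(self) -> str:
        return "unique" if self.unique else "homoplastic"

    def __str__(self) -> str:
        flag = "u" if self.unique else "h"
        return f"{self.character}({self.to_state}){flag}"


@dataclass(frozen=True)
class AncestralAssignment:
    """A fully resolved ACCTRAN reconstruction on a rooted tree.

    ``states`` maps each vertex (identified by its leaf set) to its
    resolved state vector over all characters; ``transformations`` lists
    every change, classified unique/homoplastic.  The number of
    transformations equals the Fitch length of the tree.
    """

    tree: TreeTopology
    states: Dict[FrozenSet[str], np.ndarray] = field(hash=False)
    transformations: Tuple[TransformationRecord, ...] = ()

    @property
    def length(self) -> int:
        return len(self.transformations)


def root_tree(tree: TreeTopology, outgroup: str) -> TreeTopology:
    """Root ``tree`` on the pendant branch of ``outgroup``.

    The ingroup structure is untouched; re-rooting an already rooted tree
    on the same outgroup is the identity.
    """
    if outgroup not in tree.leaves:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    if tree.rooted:
        shape = tree.shape
        if isinstance(shape, tuple) and len(shape) == 2 and outgroup in shape:
            return tree
        tree = tree.unroot()
    return TreeTopology(tree._reanchor(outgroup), rooted=True)


def _index_tree(shape) -> Tuple[List[Optional[Tuple[int, int]]], List[Optional[str]], List[int]]:
    """Flatten a nested shape into (children, leaf_label, postorder)."""
    children: List[Optional[Tuple[int, int]]] = []
    labels: List[Optional[str]] = []

    def build(node) -> int:
        idx = len(children)
        children.append(None)
        labels.append(None)
        if isinstance(node, str):
            labels[idx] = node
        else:
            if len(node) != 2:
                raise ValueError("ACCTRAN requires a binary tree")
            a = build(node[0])
            b = build(node[1])
            children[idx] = (a, b)
        return idx

    build(shape)
    post: List[int] = []

    def walk(idx: int) -> None:
        if children[idx] is not None:
            walk(children[idx][0])
            walk(children[idx][1])
        post.append(idx)

    walk(0)
    return children, labels, post


def acctran_reconstruct(rooted: TreeTopology, enc: EncodedMatrix) -> AncestralAssignment:
    """Resolve ancestral states on ``rooted`` under ACCTRAN.

    Ambiguous leaf cells are resolved to the state that avoids a change on
    their pendant branch when possible.  Raises ``ValueError`` for unrooted
    input or a leaf/taxon mismatch.
    """
    if not rooted.rooted:
        raise ValueError("acctran_reconstruct needs a rooted tree; use root_tree")
    if rooted.leaves != frozenset(enc.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    children, labels, post = _index_tree(rooted.shape)
    n_nodes = len(children)
    C = enc.n_characters
    taxon_index = {t: i for i, t in enumerate(enc.taxa)}

    # leaf sets per vertex, to name branches
    leafsets: List[FrozenSet[str]] = [frozenset()] * n_nodes
    for idx in post:
        if children[idx] is None:
            leafsets[idx] = frozenset([labels[idx]])
        else:
            a, b = children[idx]
            leafsets[idx] = leafsets[a] | leafsets[b]

    # outgroup leaf (a direct leaf child of the root), for root tie-breaks
    root_kids = children[0]
    out_leaf = None
    for k in root_kids:
        if children[k] is None:
            out_leaf = k
            break

    parent_of = np.full(n_nodes, -1, dtype=np.int64)
    for i, ch in enumerate(children):
        if ch is not None:
            parent_of[ch[0]] = i
            parent_of[ch[1]] = i

    resolved = np.zeros((n_nodes, C), dtype=np.uint8)
    changes: List[Tuple[int, int, int, int]] = []  # (node, char, from, to)

    cost = np.zeros((n_nodes, 8), dtype=np.int64)
    for c in range(C):
        # unit-cost Sankoff table over the 8 possible states
        for idx in post:
            if children[idx] is None:
                mask = int(enc.state_sets[taxon_index[labels[idx]], c])
                for s in range(8):
                    cost[idx, s] = 0 if (mask >> s) & 1 else _INF
            else:
                a, b = children[idx]
                for s in range(8):
                    ca = min(cost[a, s], cost[a].min() + 1)
                    cb = min(cost[b, s], cost[b].min() + 1)
                    cost[idx, s] = ca + cb

        def pick(idx: int, parent_state: Optional[int], prefer_mask: int) -> int:
            """Minimizing state; ties prefer a change (ACCTRAN), then
            ``prefer_mask`` members, then the lowest state."""
            extra = np.zeros(8, dtype=np.int64)
            if parent_state is not None:
                extra = np.ones(8, dtype=np.int64)
                extra[parent_state] = 0
            total = cost[idx] + extra
            best = total.min()
            cands = [s for s in range(8) if total[s] == best]
            if parent_state is not None and len(cands) > 1:
                non_parent = [s for s in cands if s != parent_state]
                if non_parent:
                    cands = non_parent
            preferred = [s for s in cands if (prefer_mask >> s) & 1]
            return (preferred or cands)[0]

        out_mask = (
            int(enc.state_sets[taxon_index[labels[out_leaf]], c])
            if out_leaf is not None
            else 0
        )
        # pre-order resolution
        order = list(reversed(post))  # parents before children
        for idx in order:
            if idx == 0:
                resolved[idx, c] = pick(idx, None, out_mask)
                continue
            # parent state already resolved
            ps = int(resolved[parent_of[idx], c])
            s = pick(idx, ps, 0)
            resolved[idx, c] = s
            if s != ps:
                changes.append((idx, c, ps, s))

    # classify uniqueness: a derived state is exclusive when it arises on a
    # single branch of the whole tree (a later reversal inside the clade
    # does not undo the single origin; a parallel origin or a re-derivation
    # of the root state does)
    by_char: Dict[int, List[Tuple[int, int, int, int]]] = {}
    for rec in changes:
        by_char.setdefault(rec[1], []).append(rec)
    records: List[TransformationRecord] = []
    for c, recs in sorted(by_char.items()):
        to_counts: Dict[int, int] = {}
        for _, _, fs, ts in recs:
            to_counts[ts] = to_counts.get(ts, 0) + 1
        root_state = int(resolved[0, c])
        for idx, _, fs, ts in recs:
            unique = to_counts[ts] == 1 and ts != root_state
            records.append(
                TransformationRecord(
                    branch=leafsets[idx],
                    character=c + 1,
                    from_state=fs,
                    to_state=ts,
                    unique=unique,
                )
            )
    records.sort(key=lambda r: (sorted(r.branch), r.character))
    states = {leafsets[i]: resolved[i].copy() for i in range(n_nodes)}
    return AncestralAssignment(
        tree=rooted, states=states, transformations=tuple(records)
    )


def list_transformations(assignment: AncestralAssignment) -> List[TransformationRecord]:
    """All character-state changes of the reconstruction, in branch order."""
    return list(assignment.transformations)


def clade_synapomorphies(
    assignment: AncestralAssignment, clade: Iterable[str]
) -> List[TransformationRecord]:
    """Changes on the branch subtending ``clade`` (its synapomorphies).

    ``clade`` must be the exact leaf set of some vertex of the rooted tree;
    records flagged unique are the exclusive synapomorphies.
    """
    target = frozenset(clade)
    if target not in assignment.states:
        raise ValueError(
            f"{sorted(target)} is not a clade of the rooted tree"
        )
    return [r for r in assignment.transformations if r.branch == target]
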