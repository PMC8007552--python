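"""Tree topologies over taxon labels.

A :class:`TreeTopology` is a binary tree shape over a set of leaf labels,
either unrooted (every internal vertex of degree 3) or rooted (every
internal vertex with two children).  Branch lengths carry no meaning under
parsimony and are not stored.

Internally a topology is held as a canonical nested-tuple shape: a leaf is
its label string, an internal vertex a pair of child shapes sorted by their
smallest descendant label.  Unrooted trees are anchored on the pendant edge
of the lexicographically smallest leaf, which makes structural equality,
hashing and bipartition extraction trivial and independent of how the tree
was produced (rotation / re-rooting invariance).
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Set, Tuple, Union

__all__ = ["TreeTopology", "NewickError"]

Shape = Union[str, tuple]


class NewickError(ValueError):
    """Raised for malformed Newick text."""


def _min_leaf(shape: Shape) -> str:
    while isinstance(shape, tuple):
        shape = min(shape, key=_min_leaf)
    return shape


def _canonical(shape: Shape) -> Shape:
    if isinstance(shape, str):
        return shape
    kids = sorted((_canonical(k) for k in shape), key=_min_leaf)
    return tuple(kids)


def _leaves(shape: Shape, out: List[str]) -> None:
    if isinstance(shape, str):
        out.append(shape)
    else:
        for k in shape:
            _leaves(k, out)


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in "()[]{}/\\,;:=*'\"`+<> \t\n")


def _quote(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class TreeTopology:
    """A rooted or unrooted binary tree shape over unique leaf labels."""

    __slots__ = ("_shape", "_rooted", "_leafset")

    def __init__(self, shape: Shape, rooted: bool = False):
        self._shape = _canonical(shape)
        self._rooted = bool(rooted)
        labels: List[str] = []
        _leaves(self._shape, labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        if len(labels) < 2:
            raise ValueError("a tree needs at least two leaves")
        self._leafset = frozenset(labels)
        if not rooted and len(labels) >= 3:
            # anchor the unrooted shape on the smallest leaf's pendant edge
            anchor = min(labels)
            if not (
                isinstance(self._shape, tuple)
                and len(self._shape) == 2
                and self._shape[0] == anchor
            ):
                self._shape = _canonical(self._reanchor(anchor))

    # -- construction -----------------------------------------------------

    def _adjacency(self) -> Tuple[Dict[int, List[int]], Dict[int, str]]:
        """Expand the nested shape into an adjacency map (root suppressed
        for unrooted trees)."""
        adj: Dict[int, List[int]] = {}
        labels: Dict[int, str] = {}
        counter = [0]

        def build(shape: Shape) -> int:
            node = counter[0]
            counter[0] += 1
            adj[node] = []
            if isinstance(shape, str):
                labels[node] = shape
            else:
                for k in shape:
                    child = build(k)
                    adj[node].append(child)
                    adj[child].append(node)
            return node

        top = build(self._shape)
        if not self._rooted and len(adj[top]) == 2:
            a, b = adj[top]
            adj[a].remove(top)
            adj[b].remove(top)
            adj[a].append(b)
            adj[b].append(a)
            del adj[top]
        return adj, labels

    def _reanchor(self, anchor: str) -> Shape:
        adj, labels = self._adjacency()
        leaf_node = next(n for n, lb in labels.items() if lb == anchor)

        def subshape(node: int, parent: int) -> Shape:
            if node in labels:
                return labels[node]
            kids = [subshape(k, node) for k in adj[node] if k != parent]
            return tuple(kids)

        neighbor = adj[leaf_node][0]
        return (anchor, subshape(neighbor, leaf_node))

    @classmethod
    def from_newick(cls, text: str, rooted: bool = False) -> "TreeTopology":
        """Parse a Newick string (branch lengths tolerated and ignored)."""
        s = text.strip()
        while s.startswith("["):  # rooting comments such as [&U] / [&R]
            end = s.find("]")
            if end < 0:
                raise NewickError(f"unterminated comment in {text!r}")
            s = s[end + 1:].lstrip()
        if s.endswith(";"):
            s = s[:-1]
        pos = [0]

        def parse_label() -> str:
            i = pos[0]
            if i < len(s) and s[i] == "'":
                out = []
                i += 1
                while i < len(s):
                    if s[i] == "'":
                        if i + 1 < len(s) and s[i + 1] == "'":
                            out.append("'")
                            i += 2
                            continue
                        i += 1
                        break
                    out.append(s[i])
                    i += 1
                pos[0] = i
                return "".join(out)
            j = i
            while j < len(s) and s[j] not in "(),:;":
                j += 1
            pos[0] = j
            return s[i:j].strip()

        def skip_length() -> None:
            if pos[0] < len(s) and s[pos[0]] == ":":
                pos[0] += 1
                j = pos[0]
                while j < len(s) and s[j] not in "(),;":
                    j += 1
                pos[0] = j

        def parse_clade() -> Shape:
            if pos[0] < len(s) and s[pos[0]] == "(":
                pos[0] += 1
                kids = [parse_clade()]
                while pos[0] < len(s) and s[pos[0]] == ",":
                    pos[0] += 1
                    kids.append(parse_clade())
                if pos[0] >= len(s) or s[pos[0]] != ")":
                    raise NewickError(f"unbalanced parentheses in {text!r}")
                pos[0] += 1
                parse_label()  # internal label, ignored
                skip_length()
                return tuple(kids)
            label = parse_label()
            skip_length()
            if not label:
                raise NewickError(f"empty leaf label in {text!r}")
            return label

        shape = parse_clade()
        if pos[0] != len(s):
            raise NewickError(f"trailing characters in {text!r}")
        if isinstance(shape, str):
            raise NewickError("a Newick tree needs at least one clade")
        if not rooted and len(shape) == 3:
            # trifurcating top vertex: standard unrooted form; anchor on one child
            shape = (shape[0], (shape[1], shape[2]))
        return cls(shape, rooted=rooted)

    # -- basic properties --------------------------------------------------

    @property
    def rooted(self) -> bool:
        return self._rooted

    @property
    def shape(self) -> Shape:
        """The canonical nested-tuple shape (leaves are label strings)."""
        return self._shape

    @property
    def leaves(self) -> FrozenSet[str]:
        return self._leafset

    @property
    def n_leaves(self) -> int:
        return len(self._leafset)

    def is_binary(self) -> bool:
        def ok(shape: Shape) -> bool:
            if isinstance(shape, str):
                return True
            return len(shape) == 2 and all(ok(k) for k in shape)

        return ok(self._shape)

    # -- structure ---------------------------------------------------------

    def clades(self) -> Set[FrozenSet[str]]:
        """Leaf sets of all internal vertices below the top (rooted reading)."""
        out: Set[FrozenSet[str]] = set()

        def walk(shape: Shape) -> FrozenSet[str]:
            if isinstance(shape, str):
                return frozenset([shape])
            here = frozenset().union(*(walk(k) for k in shape))
            out.add(here)
            return here

        walk(self._shape)
        out.discard(self._leafset)
        return out

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial bipartitions of the underlying unrooted tree.

        Each bipartition is represented by the side that excludes the
        lexicographically smallest leaf; only sides of size
        ``2 <= k <= n - 2`` are returned.
        """
        n = self.n_leaves
        anchor = min(self._leafset)
        out: Set[FrozenSet[str]] = set()
        for clade in self.clades():
            side = clade if anchor not in clade else self._leafset - clade
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return out

    def has_bipartition(self, clade: Iterable[str]) -> bool:
        """Whether the leaf set ``clade`` is one side of some branch."""
        side = frozenset(clade)
        if not side <= self._leafset:
            raise ValueError("clade contains labels not in the tree")
        other = self._leafset - side
        if len(side) < 2 or len(other) < 2:
            raise ValueError("trivial bipartition: need >= 2 leaves on each side")
        anchor = min(self._leafset)
        key = side if anchor not in side else other
        return key in self.bipartitions()

    def unroot(self) -> "TreeTopology":
        if not self._rooted:
            return self
        return TreeTopology(self._shape, rooted=False)

    # -- serialization -----------------------------------------------------

    def newick(self) -> str:
        def render(shape: Shape) -> str:
            if isinstance(shape, str):
                return _quote(shape)
            return "(" + ",".join(render(k) for k in shape) + ")"

        return render(self._shape) + ";"

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TreeTopology):
            return NotImplemented
        return self._rooted == other._rooted and self._shape == other._shape

    def __hash__(self) -> int:
        return hash((self._rooted, self._shape))

    def __repr__(self) -> str:
        kind = "rooted" if self._rooted else "unrooted"
        return f"TreeTopology({kind}, {self.n_leaves} leaves, {self.newick()})"
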