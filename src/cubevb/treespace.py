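"""Matrix and cube representations of rooted time-tree space.

A rooted ultrametric (time) tree on ``n`` taxa can be encoded as a symmetric
``n x n`` matrix whose entry ``m_ij`` holds the height of the most recent
common ancestor (MRCA) of taxa ``i`` and ``j``.  Running single-link
hierarchical clustering on the matrix recovers the tree.  Entries may be left
*unspecified* (treated as +infinity), in which case only a subset of
topologies is reachable; the *cube* pattern -- only the entries one off the
diagonal under some taxon ordering -- makes the transform a bijection between
height vectors and a restricted set of topologies.

This module provides the tree container, the matrix/cube types, the
single-link decode, the MRCA-height encode, compatible-ordering sampling, and
a brute-force enumeration oracle for how many topologies a given entry
pattern can express.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "TimeTree",
    "TreeMatrix",
    "EntryPattern",
    "CubeOrdering",
    "InvalidMatrixError",
    "IncompatibleOrderingError",
    "single_link_tree",
    "matrix_is_valid",
    "tree_to_matrix",
    "random_compatible_ordering",
    "cube_decode",
    "cube_encode",
    "count_representable_topologies",
]


class InvalidMatrixError(ValueError):
    """Raised when a matrix's adjacency graph is disconnected.

    ``components`` lists the connected components (0-based taxon indices).
    """

    def __init__(self, components: list[set[int]]):
        self.components = components
        parts = ", ".join("{" + ",".join(map(str, sorted(c))) + "}" for c in components)
        super().__init__(
            f"matrix is not valid: adjacency graph has {len(components)} "
            f"connected components: {parts}"
        )


class IncompatibleOrderingError(ValueError):
    """Raised when a taxon ordering is not obtainable by any traversal of a tree."""


# ---------------------------------------------------------------------------
# TimeTree
# ---------------------------------------------------------------------------


class TimeTree:
    """Rooted binary ultrametric tree with node heights.

    Nodes are integer ids: leaves ``0 .. n-1`` (carrying taxon labels),
    internal nodes ``n .. 2n-2``.  Leaves sit at height 0; every internal
    node is strictly higher than its children.

    Parameters
    ----------
    taxa:
        Taxon labels, position ``i`` labelling leaf node ``i``.
    parent, left, right:
        Integer arrays of length ``2n-1``; ``-1`` marks "none" (the root's
        parent, and both children of a leaf).
    height:
        Node heights in time units; ``height[i] == 0`` for leaves.
    """

    __slots__ = ("taxa", "parent", "left", "right", "height")

    def __init__(
        self,
        taxa: Sequence[str],
        parent: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        height: np.ndarray,
    ):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.height = np.asarray(height, dtype=np.float64)

    # -- basic structure ---------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        (r,) = np.flatnonzero(self.parent == -1)
        return int(r)

    @property
    def root_height(self) -> float:
        return float(self.height[self.root])

    def is_leaf(self, v: int) -> bool:
        return v < self.n_leaves

    def copy(self) -> "TimeTree":
        return TimeTree(
            list(self.taxa),
            self.parent.copy(),
            self.left.copy(),
            self.right.copy(),
            self.height.copy(),
        )

    def validate(self) -> None:
        """Check binary/ultrametric invariants; raise ``ValueError`` on failure."""
        n = self.n_leaves
        if self.parent.shape != (2 * n - 1,):
            raise ValueError("node arrays must have length 2n-1")
        if np.any(self.height[:n] != 0.0):
            raise ValueError("leaf heights must be 0")
        for v in range(n, self.n_nodes):
            l, r = self.left[v], self.right[v]
            if l < 0 or r < 0:
                raise ValueError(f"internal node {v} lacks two children")
            for c in (l, r):
                if self.height[c] >= self.height[v]:
                    raise ValueError(
                        f"node {c} (h={self.height[c]}) not below parent {v} "
                        f"(h={self.height[v]})"
                    )
                if self.parent[c] != v:
                    raise ValueError("parent/child links inconsistent")

    # -- traversal / derived quantities ------------------------------------

    def postorder_internal(self) -> list[int]:
        """Internal node ids, children before parents."""
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if self.is_leaf(v):
                continue
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                stack.append((int(self.left[v]), False))
                stack.append((int(self.right[v]), False))
        return order

    def leaf_set_below(self, v: int) -> list[int]:
        out: list[int] = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(u)
            else:
                stack.append(int(self.left[u]))
                stack.append(int(self.right[u]))
        return out

    def clades(self) -> dict[int, int]:
        """Bitmask of leaves below each internal node (leaf i -> bit i)."""
        mask = {v: 1 << v for v in range(self.n_leaves)}
        for v in self.postorder_internal():
            mask[v] = mask[int(self.left[v])] | mask[int(self.right[v])]
        return {v: mask[v] for v in range(self.n_leaves, self.n_nodes)}

    def mrca_heights(self) -> np.ndarray:
        """Full ``n x n`` matrix of pairwise MRCA heights (diagonal 0)."""
        n = self.n_leaves
        M = np.zeros((n, n))
        below: dict[int, list[int]] = {v: [v] for v in range(n)}
        for v in self.postorder_internal():
            L = below.pop(int(self.left[v]))
            R = below.pop(int(self.right[v]))
            h = self.height[v]
            M[np.ix_(L, R)] = h
            M[np.ix_(R, L)] = h
            below[v] = L + R
        return M

    def total_branch_length(self) -> float:
        """Sum of all branch lengths (tree length)."""
        non_root = self.parent >= 0
        return float(np.sum(self.height[self.parent[non_root]] - self.height[non_root]))

    def topology_key(self) -> frozenset[int]:
        """Canonical topology signature: the set of clade bitmasks."""
        return frozenset(self.clades().values())

    # -- construction / comparison -----------------------------------------

    @classmethod
    def from_merges(
        cls, taxa: Sequence[str], merges: Iterable[tuple[int, int, float]]
    ) -> "TimeTree":
        """Build from ``n-1`` (root_a, root_b, height) merge events.

        Each merge joins the current subtree roots ``root_a`` and ``root_b``
        under a new internal node at the given height.  Node ids of new
        internal nodes are ``n, n+1, ...`` in merge order.
        """
        n = len(taxa)
        size = 2 * n - 1
        parent = np.full(size, -1, dtype=np.int64)
        left = np.full(size, -1, dtype=np.int64)
        right = np.full(size, -1, dtype=np.int64)
        height = np.zeros(size)
        nxt = n
        for a, b, h in merges:
            left[nxt], right[nxt] = a, b
            parent[a] = parent[b] = nxt
            height[nxt] = h
            nxt += 1
        if nxt != size:
            raise ValueError(f"expected {n - 1} merges, got {nxt - n}")
        return cls(taxa, parent, left, right, height)

    def same_tree(self, other: "TimeTree", atol: float = 0.0) -> bool:
        """Node-for-node equality: same taxa, clades, and clade heights."""
        if self.taxa != other.taxa:
            return False
        a = {m: self.height[v] for v, m in self.clades().items()}
        b = {m: other.height[v] for v, m in other.clades().items()}
        if a.keys() != b.keys():
            return False
        return all(abs(a[m] - b[m]) <= atol for m in a)

    def newick(self, digits: int = 12) -> str:
        """Newick string with branch lengths (parent height - child height).

        Children are ordered by smallest taxon label for diff-stable output.
        """

        def fmt(x: float) -> str:
            return f"{x:.{digits}g}"

        def min_label(v: int) -> str:
            return min(self.taxa[i] for i in self.leaf_set_below(v))

        def rec(v: int) -> str:
            if self.is_leaf(v):
                return self.taxa[v]
            kids = sorted((int(self.left[v]), int(self.right[v])), key=min_label)
            parts = [
                f"{rec(c)}:{fmt(self.height[v] - self.height[c])}" for c in kids
            ]
            return "(" + ",".join(parts) + ")"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TimeTree(n={self.n_leaves}, root_height={self.root_height:.4g})"


# ---------------------------------------------------------------------------
# Matrix / pattern / cube types
# ---------------------------------------------------------------------------


@dataclass
class EntryPattern:
    """Set of specified (i, j) index pairs, i < j, over ``n`` taxa."""

    n: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        pairs = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if any(i == j or i < 0 or j >= self.n for i, j in pairs):
            raise ValueError("pattern pairs must be distinct indices within range")

    @classmethod
    def full(cls, n: int) -> "EntryPattern":
        return cls(n, frozenset(itertools.combinations(range(n), 2)))

    @classmethod
    def first_row(cls, n: int) -> "EntryPattern":
        """Caterpillar pattern: entries (0, j) for all j > 0."""
        return cls(n, frozenset((0, j) for j in range(1, n)))

    @classmethod
    def cube(cls, n: int, order: Sequence[int] | None = None) -> "EntryPattern":
        """One-off-diagonal pattern under a taxon ordering (default identity)."""
        if order is None:
            order = range(n)
        order = list(order)
        return cls(n, frozenset(
            (min(a, b), max(a, b)) for a, b in zip(order[:-1], order[1:])
        ))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.pairs))


class TreeMatrix:
    """Symmetric nonnegative matrix with unspecified (+inf) entries.

    Only upper-triangle pairs ``i < j`` are stored; the diagonal is never
    read.  Unspecified entries behave as +infinity in single-link clustering.
    """

    def __init__(self, n: int, entries: dict[tuple[int, int], float] | None = None,
                 taxa: Sequence[str] | None = None):
        self.n = n
        self.taxa = list(taxa) if taxa is not None else [f"t{i}" for i in range(n)]
        if len(self.taxa) != n:
            raise ValueError("taxa length must equal n")
        self.entries: dict[tuple[int, int], float] = {}
        if entries:
            for (i, j), v in entries.items():
                self[i, j] = v

    def __setitem__(self, key: tuple[int, int], value: float) -> None:
        i, j = key
        if i == j:
            raise ValueError("diagonal entries are ignored and cannot be set")
        if not np.isfinite(value):
            return  # unspecified
        if value <= 0:
            raise ValueError(f"matrix entries must be positive, got m[{i},{j}]={value}")
        self.entries[(min(i, j), max(i, j))] = float(value)

    def __getitem__(self, key: tuple[int, int]) -> float:
        i, j = key
        return self.entries.get((min(i, j), max(i, j)), np.inf)

    @property
    def pattern(self) -> EntryPattern:
        return EntryPattern(self.n, frozenset(self.entries))

    def dense(self) -> np.ndarray:
        M = np.full((self.n, self.n), np.inf)
        np.fill_diagonal(M, 0.0)
        for (i, j), v in self.entries.items():
            M[i, j] = M[j, i] = v
        return M

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeMatrix(n={self.n}, specified={len(self.entries)})"


@dataclass
class CubeOrdering:
    """A taxon ordering plus the n-1 gap heights between consecutive taxa.

    ``heights[i]`` is the MRCA height of taxa ``order[i]`` and
    ``order[i+1]``; together with the ordering this is a bijective encoding
    of the trees reachable within the cube.
    """

    order: list[int]
    heights: np.ndarray
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.order = [int(i) for i in self.order]
        self.heights = np.asarray(self.heights, dtype=np.float64)
        n = len(self.order)
        if self.heights.shape != (n - 1,):
            raise ValueError("need exactly n-1 gap heights")
        if np.any(self.heights <= 0):
            raise ValueError("gap heights must be positive")
        if not self.taxa:
            self.taxa = [f"t{i}" for i in range(n)]

    @property
    def n(self) -> int:
        return len(self.order)

    def to_matrix(self) -> TreeMatrix:
        M = TreeMatrix(self.n, taxa=self.taxa)
        for k in range(self.n - 1):
            M[self.order[k], self.order[k + 1]] = float(self.heights[k])
        return M


# ---------------------------------------------------------------------------
# Single-link clustering and validity
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.p[self.find(a)] = self.find(b)


def _components(n: int, pairs: Iterable[tuple[int, int]]) -> list[set[int]]:
    uf = _UnionFind(n)
    for i, j in pairs:
        uf.union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return sorted(groups.values(), key=min)


def matrix_is_valid(M: TreeMatrix) -> tuple[bool, list[set[int]]]:
    """Whether the adjacency graph over specified entries is connected.

    Returns ``(flag, components)``; the matrix decodes to a tree with finite
    branch lengths iff the graph is connected.
    """
    comps = _components(M.n, M.entries)
    return len(comps) == 1, comps


def single_link_tree(M: TreeMatrix) -> TimeTree:
    """Decode a matrix into a time tree by single-link clustering.

    Repeatedly merges the two subtrees separated by the smallest specified
    entry whose endpoints lie in different subtrees; the new internal node
    sits at that entry's value.  Exactly ``n - 1`` entries are consumed in
    nondecreasing order.  Ties are broken by smallest (i, j) pair
    lexicographically, which makes the decode deterministic.

    Raises
    ------
    InvalidMatrixError
        If the adjacency graph of specified entries is disconnected.
    """
    n = M.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    ok, comps = matrix_is_valid(M)
    if not ok:
        raise InvalidMatrixError(comps)
    # sort by (value, i, j): scanning in order is exactly single linkage
    items = sorted(M.entries.items(), key=lambda kv: (kv[1], kv[0]))
    uf = _UnionFind(n)
    root_of = list(range(n))  # component representative -> subtree root node id
    merges: list[tuple[int, int, float]] = []
    nxt = n
    for (i, j), v in items:
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            continue
        merges.append((root_of[ri], root_of[rj], v))
        uf.union(i, j)
        root_of[uf.find(i)] = nxt
        nxt += 1
        if len(merges) == n - 1:
            break
    return TimeTree.from_merges(M.taxa, merges)


def tree_to_matrix(T: TimeTree, P: EntryPattern | None = None) -> TreeMatrix:
    """Encode a tree as a matrix of MRCA heights on the given entry pattern.

    With the full pattern (default), ``single_link_tree`` recovers the tree
    exactly.
    """
    if P is None:
        P = EntryPattern.full(T.n_leaves)
    H = T.mrca_heights()
    M = TreeMatrix(T.n_leaves, taxa=T.taxa)
    for i, j in P:
        M[i, j] = float(H[i, j])
    return M


# ---------------------------------------------------------------------------
# Cube encode / decode / compatible orderings
# ---------------------------------------------------------------------------


def cube_decode(ordering: CubeOrdering) -> TimeTree:
    """Decode an ordering + gap heights into the corresponding time tree."""
    return single_link_tree(ordering.to_matrix())


def cube_encode(T: TimeTree, order: Sequence[int]) -> CubeOrdering:
    """Encode a tree as gap heights under a compatible taxon ordering.

    The gap height ``h_k`` is the MRCA height of consecutive taxa
    ``order[k]`` and ``order[k+1]``.  The ordering is *compatible* if
    decoding reproduces the tree exactly; otherwise
    ``IncompatibleOrderingError`` is raised.
    """
    order = [int(i) for i in order]
    if sorted(order) != list(range(T.n_leaves)):
        raise IncompatibleOrderingError("ordering must be a permutation of the taxa")
    H = T.mrca_heights()
    heights = np.array([H[order[k], order[k + 1]] for k in range(T.n_leaves - 1)])
    ordering = CubeOrdering(order, heights, taxa=T.taxa)
    if not cube_decode(ordering).same_tree(T):
        raise IncompatibleOrderingError(
            f"ordering {order} is not obtainable by any traversal of the tree"
        )
    return ordering


def random_compatible_ordering(T: TimeTree, rng: np.random.Generator) -> CubeOrdering:
    """Draw a uniformly random tree-compatible cube ordering.

    Performs a depth-first traversal in which each internal node's children
    are independently swapped with probability 1/2; the resulting leaf order
    is compatible with the tree and each of the ``2^(n-1)`` compatible
    orderings is equally likely (for distinct node heights).
    """
    order: list[int] = []
    gaps: list[float] = []

    def rec(v: int) -> None:
        if T.is_leaf(v):
            order.append(v)
            return
        a, b = int(T.left[v]), int(T.right[v])
        if rng.random() < 0.5:
            a, b = b, a
        rec(a)
        gaps.append(float(T.height[v]))
        rec(b)

    rec(T.root)
    return CubeOrdering(order, np.array(gaps), taxa=T.taxa)


def is_cube_compatible(T: TimeTree, order: Sequence[int]) -> bool:
    """True if the taxon ordering is obtainable by a traversal of the tree."""
    try:
        cube_encode(T, order)
        return True
    except IncompatibleOrderingError:
        return False


# ---------------------------------------------------------------------------
# Topology enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_rooted_topologies(n: int) -> list[frozenset[int]]:
    """All rooted binary topology signatures on taxa 0..n-1 (brute force).

    Returns each topology as its set of clade bitmasks.  There are
    (2n-3)!! of them; intended for small n.
    """
    if n > 8:
        raise ValueError("exhaustive enumeration limited to n <= 8")

    def build(forest: list[tuple[int, frozenset[int]]]) -> Iterator[frozenset[int]]:
        # forest items: (clade_mask, set of clades inside)
        if len(forest) == 1:
            yield forest[0][1]
            return
        for a, b in itertools.combinations(range(len(forest)), 2):
            (ma, ca), (mb, cb) = forest[a], forest[b]
            merged = (ma | mb, ca | cb | {ma | mb})
            rest = [forest[k] for k in range(len(forest)) if k not in (a, b)]
            yield from build(rest + [merged])

    seen = set(build([(1 << i, frozenset()) for i in range(n)]))
    return list(seen)


def count_representable_topologies(P: EntryPattern, n: int | None = None) -> int:
    """Count rooted binary topologies reachable from an entry pattern.

    Assigns every possible ranking (permutation of distinct values) to the
    pattern's entries, decodes each with single-link clustering, and counts
    the distinct topologies.  Because single-link clustering only compares
    entry values, rankings exhaust all generic height assignments.

    Limited to small problems (``n <= 7`` and at most 9 specified entries).
    """
    n = P.n if n is None else n
    if n != P.n:
        raise ValueError("n must match the pattern")
    if n > 7:
        raise ValueError("enumeration limited to n <= 7")
    k = len(P)
    if k > 9:
        raise ValueError("enumeration limited to patterns with <= 9 entries")
    pairs = sorted(P.pairs)
    seen: set[frozenset[int]] = set()
    for perm in itertools.permutations(range(1, k + 1)):
        M = TreeMatrix(n, {p: float(v) for p, v in zip(pairs, perm)})
        try:
            T = single_link_tree(M)
        except InvalidMatrixError:
            return 0  # disconnected pattern reaches nothing
        seen.add(T.topology_key())
    return len(seen)
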