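"""Hamming-graph combinatorics for genotype spaces.

The genotype space of sequences of length ``l`` over a ``k``-letter
alphabet is the Hamming graph H_{l,k}: one vertex per sequence, an edge
between sequences differing at exactly one position, so every vertex has
degree l(k-1).  Vertices are canonically labelled by the integers
0 .. k^l - 1 via the base-k reading of the sequence (position 0 = most
significant digit); genotype strings appear only at I/O boundaries.

Edges are never materialized for whole spaces — all counting streams over
neighbors or over vectorized per-position blocks — because H_{l,k} has
k^l * l(k-1)/2 edges.

A *bricklayer's graph* G_{n,k} is the induced subgraph on the first n
integer labels; by the sums-of-digits theorem it has exactly S_k(n) edges,
the maximum possible for any n-vertex induced subgraph (the Harper/Lindsey
edge-isoperimetric optimum).  :func:`max_edges_bruteforce` provides the
exhaustive-enumeration oracle for that optimality on tiny spaces.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenotypeSpace",
    "VertexSet",
    "BricklayerGraph",
    "EnumerationBudgetError",
    "vertex_to_genotype",
    "genotype_to_vertex",
    "neighbors",
    "edge_blocks",
    "induced_edge_count",
    "cross_edge_count",
    "boundary_edge_count",
    "connected_components",
    "bricklayer",
    "max_edges_bruteforce",
]

_DEFAULT_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class EnumerationBudgetError(RuntimeError):
    """Raised when an exhaustive enumeration would exceed its subset budget."""


@dataclass(frozen=True)
class GenotypeSpace:
    """The Hamming graph H_{l,k}: alphabet size k, sequence length l.

    ``symbols`` orders the alphabet and defines the vertex labelling; it
    defaults to '0123...' for k <= 36.  Instances are immutable and
    hashable so they can key caches.
    """

    k: int
    length: int
    symbols: str = ""

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("alphabet size k must be >= 2")
        if self.length < 1:
            raise ValueError("sequence length must be >= 1")
        if not self.symbols:
            if self.k > len(_DEFAULT_SYMBOLS):
                raise ValueError("provide explicit symbols for k > 36")
            object.__setattr__(self, "symbols", _DEFAULT_SYMBOLS[: self.k])
        if len(self.symbols) != self.k or len(set(self.symbols)) != self.k:
            raise ValueError("symbols must be k distinct characters")

    @property
    def n_vertices(self) -> int:
        return self.k**self.length

    @property
    def degree(self) -> int:
        return self.length * (self.k - 1)

    @property
    def total_edges(self) -> int:
        return self.n_vertices * self.degree // 2

    def _check_label(self, label: int) -> None:
        if not 0 <= label < self.n_vertices:
            raise ValueError(f"vertex label {label} outside [0, {self.n_vertices})")


def vertex_to_genotype(label: int, space: GenotypeSpace) -> str:
    """Genotype string of an integer label (base-k digits, MSD first)."""
    space._check_label(label)
    out = []
    for _ in range(space.length):
        label, r = divmod(label, space.k)
        out.append(space.symbols[r])
    return "".join(reversed(out))


def genotype_to_vertex(sequence: str, space: GenotypeSpace) -> int:
    """Integer label of a genotype string; inverse of vertex_to_genotype."""
    if len(sequence) != space.length:
        raise ValueError(
            f"sequence {sequence!r} has length {len(sequence)}, expected {space.length}"
        )
    label = 0
    for ch in sequence:
        try:
            d = space.symbols.index(ch)
        except ValueError:
            raise ValueError(f"unknown symbol {ch!r} for alphabet {space.symbols!r}") from None
        label = label * space.k + d
    return label


def neighbors(label: int, space: GenotypeSpace) -> list[int]:
    """The l(k-1) single-mutation neighbors of a vertex."""
    space._check_label(label)
    out = []
    place = 1
    for _ in range(space.length):
        digit = (label // place) % space.k
        base = label - digit * place
        for d in range(space.k):
            if d != digit:
                out.append(base + d * place)
        place *= space.k
    return out


def edge_blocks(space: GenotypeSpace) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (u, v) label arrays covering every Hamming edge exactly once.

    Iterates positions and ordered digit pairs a < b; memory stays O(k^l)
    per block instead of O(|E|) overall.
    """
    verts = np.arange(space.n_vertices, dtype=np.int64)
    place = 1
    for _ in range(space.length):
        digit = (verts // place) % space.k
        for a in range(space.k):
            u = verts[digit == a]
            for b in range(a + 1, space.k):
                yield u, u + (b - a) * place
        place *= space.k


@dataclass(frozen=True)
class VertexSet:
    """A subset of vertex labels of a genotype space (e.g. a neutral set)."""

    space: GenotypeSpace
    vertices: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", frozenset(int(v) for v in self.vertices))
        for v in self.vertices:
            self.space._check_label(v)

    def __len__(self) -> int:
        return len(self.vertices)

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.vertices))


def _as_set(S: VertexSet | Iterable[int], space: GenotypeSpace | None = None) -> tuple[GenotypeSpace, frozenset[int]]:
    if isinstance(S, VertexSet):
        return S.space, S.vertices
    if space is None:
        raise ValueError("space required when passing a bare vertex iterable")
    return space, frozenset(int(v) for v in S)


def induced_edge_count(S: VertexSet | Iterable[int], space: GenotypeSpace | None = None) -> int:
    """Number of Hamming edges with both endpoints in S (each counted once)."""
    space, verts = _as_set(S, space)
    count = 0
    for u in verts:
        for v in neighbors(u, space):
            if v > u and v in verts:
                count += 1
    return count


def cross_edge_count(
    A: VertexSet | Iterable[int],
    B: VertexSet | Iterable[int],
    space: GenotypeSpace | None = None,
) -> int:
    """|E(A, B)|: edges with one endpoint in A and the other in B.

    A and B must be disjoint; each cross edge is counted once.
    """
    space_a, va = _as_set(A, space)
    space_b, vb = _as_set(B, space)
    if space_a != space_b:
        raise ValueError("A and B live in different genotype spaces")
    if va & vb:
        raise ValueError("A and B must be disjoint for cross-edge counting")
    small, other = (va, vb) if len(va) <= len(vb) else (vb, va)
    return sum(1 for u in small for v in neighbors(u, space_a) if v in other)


def boundary_edge_count(S: VertexSet | Iterable[int], space: GenotypeSpace | None = None) -> int:
    """Edges from S to its complement: l(k-1)|S| - 2|E(S)|."""
    space, verts = _as_set(S, space)
    return space.degree * len(verts) - 2 * induced_edge_count(verts, space)


def connected_components(
    S: VertexSet | Iterable[int], space: GenotypeSpace | None = None
) -> list[VertexSet]:
    """Maximal single-mutation-connected subsets of S.

    Iterative BFS (no recursion); components are ordered by their smallest
    member for reproducible output.
    """
    space, verts = _as_set(S, space)
    unseen = set(verts)
    out: list[VertexSet] = []
    for seed in sorted(verts):
        if seed not in unseen:
            continue
        queue = deque([seed])
        unseen.discard(seed)
        comp = {seed}
        while queue:
            u = queue.popleft()
            for v in neighbors(u, space):
                if v in unseen:
                    unseen.discard(v)
                    comp.add(v)
                    queue.append(v)
        out.append(VertexSet(space, frozenset(comp)))
    return out


@dataclass(frozen=True)
class BricklayerGraph:
    """Induced subgraph on labels {0, ..., n-1}; edge-isoperimetric optimum."""

    space: GenotypeSpace
    n: int
    edge_count: int = field(default=-1)

    def __post_init__(self) -> None:
        if not 0 <= self.n <= self.space.n_vertices:
            raise ValueError(f"n must lie in [0, {self.space.n_vertices}]")

    @property
    def vertices(self) -> range:
        return range(self.n)


def bricklayer(n: int, space: GenotypeSpace) -> BricklayerGraph:
    """Bricklayer's graph on the first n labels, edges counted directly.

    The edge count is obtained by pair counting (neighbor streaming), not
    from S_k(n), so that equality with the sums-of-digits function remains
    an independently checkable theorem rather than an assumption.
    """
    if not 0 <= n <= space.n_vertices:
        raise ValueError(f"n must lie in [0, {space.n_vertices}]")
    count = 0
    for u in range(n):
        for v in neighbors(u, space):
            if u < v < n:
                count += 1
    return BricklayerGraph(space=space, n=n, edge_count=count)


def max_edges_bruteforce(n: int, space: GenotypeSpace, budget: int = 10**7) -> int:
    """Exhaustive maximum of |E(G)| over all n-vertex induced subgraphs.

    Enumerates subsets in lexicographic order with adjacency bitmasks.
    Refuses explicitly (EnumerationBudgetError) if C(k^l, n) exceeds
    ``budget`` — the oracle must be exact or absent, never sampled.
    """
    N = space.n_vertices
    if not 0 <= n <= N:
        raise ValueError(f"n must lie in [0, {N}]")
    n_subsets = math.comb(N, n)
    if n_subsets > budget:
        raise EnumerationBudgetError(
            f"C({N}, {n}) = {n_subsets} subsets exceeds enumeration budget {budget}"
        )
    adj = [0] * N
    for u in range(N):
        for v in neighbors(u, space):
            adj[u] |= 1 << v
    best = 0
    for subset in combinations(range(N), n):
        mask = 0
        for v in subset:
            mask |= 1 << v
        edges = sum((adj[v] & mask).bit_count() for v in subset) // 2
        if edges > best:
            best = edges
    return best
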