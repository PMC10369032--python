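"""Genotype-phenotype map analysis: neutral sets, components, transitions.

A GP map assigns every vertex of the Hamming graph H_{l,k} (every
genotype) exactly one phenotype label, so phenotype neutral sets partition
the graph.  This module computes, for a complete map,

* per-phenotype statistics: neutral-set size n_p, frequency f_p = n_p/k^l,
  internal edge count, robustness rho_p = 2|E|/(l(k-1) n_p), and the
  neutral-component decomposition with exact (integer) attainment flags
  against the bricklayer maximum S_k(n) and the connected minimum n - 1,
* the phenotype transition matrix phi with phi[t, s] =
  |E(G_s, G_t)|/(l(k-1)|V(G_s)|) for t != s and rho_s on the diagonal
  (the factor-2 convention: internal edges are counted from both ends),
  which is column-stochastic and satisfies detailed balance
  phi_ts f_s = phi_st f_t,
* the per-phenotype multi-component deviation table, and
* two generators: the random null model (genotypes assigned to phenotypes
  uniformly at random with fixed neutral-set sizes) and the
  bricklayer-packed map (consecutive integer blocks, the first of which
  attains the robustness maximum by construction).

Phenotype labels are ordered by descending neutral-set size, ties broken
lexicographically, so all matrices and tables are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bounds, hamming
from .hamming import GenotypeSpace
from .sumdigits import sums_of_digits

__all__ = [
    "GPMap",
    "GPMapError",
    "PhenotypeStats",
    "ComponentStats",
    "TransitionMatrix",
    "read_gpmap",
    "write_gpmap",
    "phenotype_stats",
    "transition_matrix",
    "deviation_table",
    "generate_random_null",
    "generate_bricklayer_packed",
]


class GPMapError(ValueError):
    """Malformed or incomplete genotype-phenotype map."""


@dataclass(frozen=True)
class GPMap:
    """A complete map from every vertex of a genotype space to a phenotype.

    ``codes[v]`` is the index into ``labels`` of vertex v's phenotype;
    ``labels`` is ordered by descending neutral-set size (ties
    lexicographic).
    """

    space: GenotypeSpace
    codes: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int32)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "labels", tuple(self.labels))
        if codes.shape != (self.space.n_vertices,):
            raise GPMapError(
                f"codes must cover all {self.space.n_vertices} vertices, got {codes.shape}"
            )
        if codes.min(initial=0) < 0 or codes.max(initial=0) >= len(self.labels):
            raise GPMapError("phenotype codes out of range")

    @classmethod
    def from_vertex_labels(cls, space: GenotypeSpace, labels_per_vertex) -> "GPMap":
        """Build a map from an array of per-vertex phenotype labels."""
        arr = np.asarray(labels_per_vertex, dtype=object)
        if arr.shape != (space.n_vertices,):
            raise GPMapError("need one phenotype label per vertex")
        uniq, counts = np.unique(arr.astype(str), return_counts=True)
        order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
        labels = tuple(uniq[i] for i in order)
        rank = {lab: i for i, lab in enumerate(labels)}
        codes = np.fromiter((rank[x] for x in arr.astype(str)), dtype=np.int32, count=arr.size)
        return cls(space=space, codes=codes, labels=labels)

    @property
    def sizes(self) -> np.ndarray:
        """Neutral-set sizes n_p, in label order."""
        return np.bincount(self.codes, minlength=len(self.labels))

    @property
    def frequencies(self) -> np.ndarray:
        return self.sizes / self.space.n_vertices

    def vertices_of(self, label: str) -> np.ndarray:
        """Sorted vertex labels of a phenotype's neutral set."""
        try:
            code = self.labels.index(label)
        except ValueError:
            raise GPMapError(f"unknown phenotype label {label!r}") from None
        return np.flatnonzero(self.codes == code)

    def relabel(self, mapping: dict[str, str]) -> "GPMap":
        """New map with phenotype labels replaced per ``mapping`` (total)."""
        missing = [lab for lab in self.labels if lab not in mapping]
        if missing:
            raise GPMapError(f"relabeling is not total; missing {missing}")
        new = np.array([mapping[lab] for lab in self.labels], dtype=object)
        return GPMap.from_vertex_labels(self.space, new[self.codes])


# ---------------------------------------------------------------------------
# I/O: two-column TSV, '#' comments, optional header
# ---------------------------------------------------------------------------


def read_gpmap(
    path,
    symbols: str | None = None,
    default_phenotype: str | None = None,
) -> GPMap:
    """Read a genotype<TAB>phenotype table into a complete GPMap.

    The alphabet is inferred from the observed symbols (sorted) unless
    ``symbols`` is given.  Missing genotypes are an error unless
    ``default_phenotype`` supplies a fill label (e.g. "." for unfolded);
    duplicate rows are accepted if consistent, rejected otherwise.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GPMapError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0].lower() == "genotype" and rows[0][1].lower() == "phenotype":
        rows = rows[1:]
    if not rows:
        raise GPMapError(f"{path}: no genotype rows found")
    length = len(rows[0][0])
    for geno, _ in rows:
        if len(geno) != length:
            raise GPMapError(
                f"{path}: ragged genotype lengths ({len(geno)} vs {length} for {geno!r})"
            )
    if symbols is None:
        symbols = "".join(sorted({ch for geno, _ in rows for ch in geno}))
    space = GenotypeSpace(k=len(symbols), length=length, symbols=symbols)
    assignment: dict[int, str] = {}
    n_dup = 0
    for geno, pheno in rows:
        v = hamming.genotype_to_vertex(geno, space)
        if v in assignment:
            if assignment[v] != pheno:
                raise GPMapError(
                    f"{path}: genotype {geno!r} assigned to both "
                    f"{assignment[v]!r} and {pheno!r}"
                )
            n_dup += 1
        else:
            assignment[v] = pheno
    if n_dup:
        warnings.warn(f"{path}: {n_dup} duplicate consistent rows accepted", stacklevel=2)
    if len(assignment) < space.n_vertices:
        if default_phenotype is None:
            raise GPMapError(
                f"{path}: map is not total ({len(assignment)} of "
                f"{space.n_vertices} genotypes); supply default_phenotype to fill"
            )
        per_vertex = np.array(
            [assignment.get(v, default_phenotype) for v in range(space.n_vertices)],
            dtype=object,
        )
    else:
        per_vertex = np.empty(space.n_vertices, dtype=object)
        for v, lab in assignment.items():
            per_vertex[v] = lab
    return GPMap.from_vertex_labels(space, per_vertex)


def write_gpmap(gpmap: GPMap, path) -> None:
    """Write a GPMap as genotype<TAB>phenotype rows (ascending labels)."""
    with open(path, "w") as fh:
        fh.write("# genotype\tphenotype\n")
        for v in range(gpmap.space.n_vertices):
            geno = hamming.vertex_to_genotype(v, gpmap.space)
            fh.write(f"{geno}\t{gpmap.labels[gpmap.codes[v]]}\n")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentStats:
    """One neutral component: size, edges, robustness, attainment flags."""

    size: int
    edge_count: int
    rho: float
    attains_max: bool  # edge_count == S_k(size), exact integers
    attains_min: bool  # edge_count == size - 1 (tree / path / star)


@dataclass(frozen=True)
class PhenotypeStats:
    """Whole-neutral-set statistics for one phenotype."""

    label: str
    n: int
    f: float
    edge_count: int
    rho: float
    components: tuple[ComponentStats, ...]


def _pair_count_matrix(gpmap: GPMap) -> np.ndarray:
    """M[a, b] = number of Hamming edges with endpoint phenotypes (a, b).

    Each unordered edge is counted exactly once (internal edges land on
    the diagonal); built by streaming vectorized edge blocks, never
    materializing the full edge list.
    """
    P = len(gpmap.labels)
    M = np.zeros((P, P), dtype=np.int64)
    for u, v in hamming.edge_blocks(gpmap.space):
        np.add.at(M, (gpmap.codes[u], gpmap.codes[v]), 1)
    return M


def phenotype_stats(gpmap: GPMap) -> list[PhenotypeStats]:
    """Per-phenotype sizes, robustness and component decomposition.

    Attainment of the bricklayer maximum and the connected minimum is
    decided by exact integer comparison of edge counts, never on floats.
    """
    space = gpmap.space
    M = _pair_count_matrix(gpmap)
    sizes = gpmap.sizes
    out: list[PhenotypeStats] = []
    for i, label in enumerate(gpmap.labels):
        n_p = int(sizes[i])
        edge_count = int(M[i, i])
        rho = 2.0 * edge_count / (space.degree * n_p) if n_p else 0.0
        comps = []
        for comp in hamming.connected_components(gpmap.vertices_of(label), space):
            size = len(comp)
            edges = hamming.induced_edge_count(comp)
            comps.append(
                ComponentStats(
                    size=size,
                    edge_count=edges,
                    rho=2.0 * edges / (space.degree * size),
                    attains_max=edges == sums_of_digits(size, space.k),
                    attains_min=edges == size - 1,
                )
            )
        out.append(
            PhenotypeStats(
                label=label,
                n=n_p,
                f=n_p / space.n_vertices,
                edge_count=edge_count,
                rho=rho,
                components=tuple(comps),
            )
        )
    return out


@dataclass(frozen=True)
class TransitionMatrix:
    """Phenotype transition probabilities with robustness on the diagonal.

    ``phi[t, s]`` is the probability that a random single-character
    mutation of a random phenotype-s genotype yields phenotype t; columns
    sum to one (every mutation lands somewhere) and detailed balance
    phi_ts f_s = phi_st f_t holds.
    """

    labels: tuple[str, ...]
    f: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        P = len(self.labels)
        if self.f.shape != (P,) or self.phi.shape != (P, P):
            raise ValueError("inconsistent matrix dimensions")

    @property
    def rho(self) -> np.ndarray:
        """Diagonal robustness values."""
        return np.diag(self.phi)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        """Square CSV with a header row and column of phenotype labels."""
        self.to_dataframe().to_csv(path, index_label="phenotype", float_format="%.12g")

    @classmethod
    def from_csv(cls, path, frequencies=None) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        f = np.asarray(frequencies, dtype=float) if frequencies is not None else np.full(len(df), np.nan)
        return cls(labels=tuple(df.index), f=f, phi=df.to_numpy())


def transition_matrix(gpmap: GPMap) -> TransitionMatrix:
    """Build the transition matrix phi of a complete GP map.

    phi[t, s] = |E(G_s, G_t)| / (l(k-1) |V(G_s)|) off the diagonal and
    phi[s, s] = rho_s = 2|E(G_s)| / (l(k-1) |V(G_s)|) — the prefactor 2
    because internal edges connect two genotypes of the same set.
    """
    space = gpmap.space
    M = _pair_count_matrix(gpmap)
    sizes = gpmap.sizes.astype(float)
    cross = M + M.T  # symmetric cross-edge counts; diagonal doubles internal
    phi = cross / (space.degree * sizes[np.newaxis, :])
    return TransitionMatrix(labels=gpmap.labels, f=sizes / space.n_vertices, phi=phi)


def deviation_table(gpmap: GPMap) -> pd.DataFrame:
    """Per-phenotype deviation from the single-component optimum vs its bound.

    lhs = rho_max(n_p) - (1/n_p) sum_i n_i rho(A_i) over the actual
    neutral components A_i; rhs is the multi-component lower bound from
    the sums-of-digits superadditivity (proven only for m <= k
    components).  Columns: phenotype, n, m, lhs, rhs, proven.
    """
    space = gpmap.space
    rows = []
    for st in phenotype_stats(gpmap):
        comp_sizes = [c.size for c in st.components]
        weighted = sum(c.size * c.rho for c in st.components) / st.n
        split = bounds.ComponentSplit(sizes=tuple(comp_sizes), k=space.k)
        rows.append(
            {
                "phenotype": st.label,
                "n": st.n,
                "m": split.m,
                "lhs": bounds.rho_max(st.n, space) - weighted,
                "rhs": bounds.multicomponent_deviation_bound(split, space),
                "proven": split.proven,
            }
        )
    return pd.DataFrame(rows, columns=["phenotype", "n", "m", "lhs", "rhs", "proven"])


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _check_sizes(space: GenotypeSpace, sizes) -> list[int]:
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("all neutral-set sizes must be >= 1")
    if sum(sizes) != space.n_vertices:
        raise ValueError(
            f"sizes sum to {sum(sizes)}, but the space has {space.n_vertices} vertices"
        )
    return sizes


def generate_random_null(space: GenotypeSpace, sizes, seed: int, labels=None) -> GPMap:
    """Random null model: uniform random partition with fixed set sizes.

    Genotypes are attributed to phenotypes uniformly at random under the
    constraint that the neutral-set sizes are exactly ``sizes``.  The same
    seed always yields the identical map.
    """
    sizes = _check_sizes(space, sizes)
    if labels is None:
        labels = [f"P{i + 1}" for i in range(len(sizes))]
    if len(labels) != len(sizes) or len(set(labels)) != len(labels):
        raise ValueError("labels must be distinct and match sizes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(space.n_vertices)
    per_vertex = np.empty(space.n_vertices, dtype=object)
    start = 0
    for lab, size in zip(labels, sizes):
        per_vertex[perm[start : start + size]] = lab
        start += size
    return GPMap.from_vertex_labels(space, per_vertex)


def generate_bricklayer_packed(space: GenotypeSpace, sizes, labels=None) -> GPMap:
    """Consecutive-integer-block map; the first block is a bricklayer's graph.

    Phenotype j occupies labels [offset_j, offset_j + size_j); the first
    phenotype therefore attains the maximum robustness 2 S_k(n)/(n l (k-1))
    by construction.
    """
    sizes = _check_sizes(space, sizes)
    if labels is None:
        labels = [f"P{i + 1}" for i in range(len(sizes))]
    if len(labels) != len(sizes) or len(set(labels)) != len(labels):
        raise ValueError("labels must be distinct and match sizes")
    per_vertex = np.empty(space.n_vertices, dtype=object)
    start = 0
    for lab, size in zip(labels, sizes):
        per_vertex[start : start + size] = lab
        start += size
    return GPMap.from_vertex_labels(space, per_vertex)
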