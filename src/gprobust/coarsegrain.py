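"""Phenotype coarse-graining and critical merge thresholds.

Merging a set S of phenotypes into one compound phenotype combines their
neutral sets.  Frequencies add, f_S = sum_s f_s, and with the convention
phi_ss = rho_s the merged transition probabilities and robustness share one
frequency-weighted form

    phi_TS = sum_{s in S} sum_{t in T} phi_ts f_s / f_S       (T != S)
    rho_S  = sum_{s in S} sum_{r in S} phi_rs f_s / f_S,

so the coarse-grained matrix is computed uniformly over group pairs.  If S
is the set of all phenotypes of a complete map, rho_S = 1: every mutation
stays inside the union.

For a pairwise merge of phenotypes p, q (f_q <= f_p, beta = f_q/f_p) whose
robustnesses sit Delta_p, Delta_q below the asymptotic optimal line
rho = 1 + log_k(f)/l, the merged robustness is linear in the transition
probability phi_qp.  Requiring it to stay within
[1 + log_k(f_p+f_q)/l - max(Delta), 1 + log_k(f_p+f_q)/l - min(Delta)]
yields closed-form critical bounds on phi_qp:

    phi_* = [F log_k F - f_p log_k f_p - f_q log_k f_q
             + l (f_p Delta_p + f_q Delta_q - F Delta_*)] / (2 l f_p),

with F = f_p + f_q and Delta_* = min(Delta_p, Delta_q) for the upper bound,
max for the lower.  Observed pairs are classified as undershooting,
within, or overshooting these bounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpmap import GPMap, GPMapError, TransitionMatrix, transition_matrix
from .hamming import GenotypeSpace

__all__ = [
    "Partition",
    "read_partition",
    "write_partition",
    "coarse_grain",
    "coarse_grain_map",
    "pairwise_merged_rho",
    "merged_rho_asymptotic",
    "delta_from_rho",
    "critical_phi_bounds",
    "classify_pairs",
    "MergePair",
]


@dataclass(frozen=True)
class Partition:
    """Total assignment of phenotype labels to coarse-grained group labels."""

    mapping: dict[str, str]

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def validate_total(self, labels) -> None:
        missing = [lab for lab in labels if lab not in self.mapping]
        if missing:
            raise GPMapError(f"partition does not cover phenotypes {missing}")

    @classmethod
    def identity(cls, labels) -> "Partition":
        return cls(mapping={lab: lab for lab in labels})

    @classmethod
    def all_to_one(cls, labels, group: str = "ALL") -> "Partition":
        return cls(mapping={lab: group for lab in labels})


def read_partition(path) -> Partition:
    """Read a two-column TSV (phenotype label -> group label)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GPMapError(f"{path}:{lineno}: expected two columns")
            if parts[0] in mapping and mapping[parts[0]] != parts[1]:
                raise GPMapError(f"{path}:{lineno}: conflicting group for {parts[0]!r}")
            mapping[parts[0]] = parts[1]
    if not mapping:
        raise GPMapError(f"{path}: empty partition")
    return Partition(mapping=mapping)


def write_partition(partition: Partition, path) -> None:
    with open(path, "w") as fh:
        fh.write("# phenotype\tgroup\n")
        for pheno, group in partition.mapping.items():
            fh.write(f"{pheno}\t{group}\n")


def coarse_grain(matrix: TransitionMatrix, partition: Partition) -> TransitionMatrix:
    """Coarse-grain a transition matrix by merging phenotype groups.

    Group frequencies add; every entry (diagonal included, thanks to the
    phi_ss = rho_s convention) is the frequency-weighted average
    sum_{s in S, t in T} phi_ts f_s / f_S.  Output groups are ordered by
    descending merged frequency (ties lexicographic), matching the
    ordering convention of maps, so matrix-level and map-level
    coarse-graining agree entry-wise.
    """
    partition.validate_total(matrix.labels)
    unknown = [lab for lab in partition.mapping if lab not in matrix.labels]
    if unknown:
        raise GPMapError(f"partition mentions unknown phenotypes {unknown}")
    group_f: dict[str, float] = {}
    members: dict[str, list[int]] = {}
    for i, lab in enumerate(matrix.labels):
        g = partition.mapping[lab]
        group_f[g] = group_f.get(g, 0.0) + float(matrix.f[i])
        members.setdefault(g, []).append(i)
    groups = sorted(group_f, key=lambda g: (-group_f[g], g))
    G = len(groups)
    f_out = np.array([group_f[g] for g in groups])
    phi_out = np.zeros((G, G))
    weighted = matrix.phi * matrix.f[np.newaxis, :]  # phi_ts * f_s
    for sj, S in enumerate(groups):
        cols = members[S]
        for ti, T in enumerate(groups):
            phi_out[ti, sj] = weighted[np.ix_(members[T], cols)].sum() / f_out[sj]
    return TransitionMatrix(labels=tuple(groups), f=f_out, phi=phi_out)


def coarse_grain_map(gpmap: GPMap, partition: Partition) -> TransitionMatrix:
    """Relabel phenotypes by group and rebuild the transition matrix.

    Entry-wise equal (to floating precision) to coarse-graining the
    original matrix — the two routes are an internal consistency check.
    """
    partition.validate_total(gpmap.labels)
    merged = gpmap.relabel(dict(partition.mapping))
    return transition_matrix(merged)


# ---------------------------------------------------------------------------
# Pairwise merges and critical transition-probability thresholds
# ---------------------------------------------------------------------------


def pairwise_merged_rho(
    f_p: float, f_q: float, rho_p: float, rho_q: float, phi_qp: float
) -> float:
    """Exact robustness of the merge of two phenotypes.

    rho_S = (rho_p f_p + rho_q f_q + 2 phi_qp f_p) / (f_p + f_q); the
    cross-edge term enters twice because merged-internal edges are counted
    from both ends (phi_qp f_p = phi_pq f_q).
    """
    if f_p <= 0 or f_q <= 0:
        raise ValueError("frequencies must be positive")
    return (rho_p * f_p + rho_q * f_q + 2.0 * phi_qp * f_p) / (f_p + f_q)


def _logk(x: float, k: int) -> float:
    return math.log(x) / math.log(k)


def delta_from_rho(rho: float, f: float, space: GenotypeSpace) -> float:
    """Displacement below the asymptotic optimum: Delta = 1 + log_k(f)/l - rho.

    Clipped at zero (with a warning) when a measured robustness exceeds
    the asymptotic line, which can happen for very small neutral sets
    where the line dips below the exact maximum.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    delta = 1.0 + _logk(f, space.k) / space.length - rho
    if delta < 0:
        warnings.warn(
            f"measured robustness {rho:.4g} exceeds the asymptotic optimum at "
            f"f={f:.4g}; clipping Delta to 0",
            stacklevel=2,
        )
        return 0.0
    return delta


def merged_rho_asymptotic(
    f_p: float,
    f_q: float,
    delta_p: float,
    delta_q: float,
    phi_qp: float,
    space: GenotypeSpace,
) -> float:
    """High-robustness approximation of the merged robustness.

    Substitutes rho_i = 1 + log_k(f_i)/l - Delta_i into the exact pairwise
    merge formula; linear in phi_qp.  This is the function whose level
    crossings define the critical thresholds.
    """
    k, ell = space.k, space.length
    F = f_p + f_q
    return (
        1.0
        - (f_p * delta_p + f_q * delta_q) / F
        + (f_p * _logk(f_p, k) + f_q * _logk(f_q, k) + 2.0 * ell * phi_qp * f_p)
        / (ell * F)
    )


def critical_phi_bounds(
    f_p: float,
    f_q: float,
    delta_p: float,
    delta_q: float,
    space: GenotypeSpace,
) -> tuple[float, float]:
    """Critical transition probabilities (phi_lower, phi_upper) for a merge.

    Solving the linear merged-robustness approximation for phi_qp at the
    target levels 1 + log_k(f_p+f_q)/l - max(Delta) (lower) and
    ... - min(Delta) (upper).  Inputs are swapped internally if needed so
    that f_q <= f_p (beta = f_q/f_p in (0, 1]); phi_qp is the transition
    probability out of the more frequent phenotype p.
    """
    if f_p <= 0 or f_q <= 0:
        raise ValueError("frequencies must be positive")
    if delta_p < 0 or delta_q < 0:
        raise ValueError("Delta displacements must be non-negative")
    if f_q > f_p:
        f_p, f_q = f_q, f_p
        delta_p, delta_q = delta_q, delta_p
    k, ell = space.k, space.length
    F = f_p + f_q
    entropy = F * _logk(F, k) - f_p * _logk(f_p, k) - f_q * _logk(f_q, k)
    weighted = f_p * delta_p + f_q * delta_q

    def solve(target_delta: float) -> float:
        return (entropy + ell * (weighted - F * target_delta)) / (2.0 * ell * f_p)

    phi_upper = solve(min(delta_p, delta_q))
    phi_lower = solve(max(delta_p, delta_q))
    return phi_lower, phi_upper


@dataclass(frozen=True)
class MergePair:
    """Classification record for one unordered phenotype pair."""

    p: str
    q: str
    f_p: float
    f_q: float
    beta: float
    delta_p: float
    delta_q: float
    phi_qp: float
    phi_lower: float
    phi_upper: float
    classification: str


def classify_pairs(matrix: TransitionMatrix, space: GenotypeSpace) -> pd.DataFrame:
    """Classify every unordered phenotype pair against the merge thresholds.

    For each pair, p is the more frequent phenotype, Delta values come
    from the observed diagonal robustness (clipped at 0), phi_qp is the
    observed transition probability out of p, and the classification is
    'undershoot', 'within' or 'overshoot' relative to
    (phi_lower, phi_upper).  Columns follow the report layout
    (p, q, f_p, f_q, beta, delta_p, delta_q, phi_qp, phi_lower,
    phi_upper, class).
    """
    labels = matrix.labels
    f = matrix.f
    rho = matrix.rho
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        deltas = [delta_from_rho(float(rho[i]), float(f[i]), space) for i in range(len(labels))]
    records = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            # matrix labels are ordered by descending f, so i is the more frequent
            p_idx, q_idx = (i, j) if f[i] >= f[j] else (j, i)
            f_p, f_q = float(f[p_idx]), float(f[q_idx])
            phi_qp = float(matrix.phi[q_idx, p_idx])
            lo, hi = critical_phi_bounds(f_p, f_q, deltas[p_idx], deltas[q_idx], space)
            if phi_qp < lo:
                cls = "undershoot"
            elif phi_qp > hi:
                cls = "overshoot"
            else:
                cls = "within"
            records.append(
                {
                    "p": labels[p_idx],
                    "q": labels[q_idx],
                    "f_p": f_p,
                    "f_q": f_q,
                    "beta": f_q / f_p,
                    "delta_p": deltas[p_idx],
                    "delta_q": deltas[q_idx],
                    "phi_qp": phi_qp,
                    "phi_lower": lo,
                    "phi_upper": hi,
                    "class": cls,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "p", "q", "f_p", "f_q", "beta", "delta_p", "delta_q",
            "phi_qp", "phi_lower", "phi_upper", "class",
        ],
    )
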