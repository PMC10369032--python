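"""Robustness curves and inequalities for neutral sets.

The mutational robustness of a phenotype with neutral set G inside the
Hamming graph H_{l,k} is rho = 2|E(G)| / (l(k-1)|V(G)|).  For a set of n
genotypes the attainable extremes and reference values are

* maximum:   rho_max(n) = 2 S_k(n) / (n l (k-1))  (bricklayer's graph),
  with the blancmange-like continuous interpolation
  rho_max(n) = [log_k n - g_k(k^{{log_k n}-1})/(k-1)] / l,
* sandwich:  log_k(n)/l + 2 A_k/((k-1)l)  <=  rho_max(n)  <=  log_k(n)/l,
  the upper line being the familiar empirical scaling 1 + log_k(f)/l,
* minimum (single connected component): rho_min(n) = (2/(l(k-1)))(1 - 1/n),
* random-null expectation: rho_null(n) = f = n/k^l.

For neutral sets split into several components the sums-of-digits
superadditivity inequality

    sum_i S_k(n_i) + sum_{i=1}^{k-1} (k-i) n_i  <=  S_k(sum_i n_i)

(ascending n_1 <= ... <= n_k) yields a lower bound on how far such a set
must fall below the single-component optimum; it is proven for at most k
components and flagged unproven beyond that.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hamming import GenotypeSpace
from .sumdigits import (
    _floor_log,
    alphabet_constant,
    delange_g,
    sums_of_digits,
    sums_of_digits_range,
)

__all__ = [
    "rho_max",
    "rho_max_continuous",
    "rho_bounds",
    "lower_bound_correction",
    "rho_min",
    "rho_null",
    "percolation_threshold",
    "giant_component_threshold",
    "SplitInequality",
    "split_inequality",
    "ComponentSplit",
    "multicomponent_deviation_bound",
    "robustness_curve",
    "continuous_curve",
]


def _check_n(n, space: GenotypeSpace) -> None:
    if not 1 <= n <= space.n_vertices:
        raise ValueError(f"n must lie in [1, {space.n_vertices}], got {n}")


def rho_max(n: int, space: GenotypeSpace) -> float:
    """Maximum robustness of an n-genotype neutral set: 2 S_k(n)/(n l (k-1)).

    Exact integer S_k(n); attained by the bricklayer's graph on the first
    n labels.
    """
    _check_n(n, space)
    n = int(n)
    return 2.0 * sums_of_digits(n, space.k) / (n * space.degree)


def rho_max_continuous(n: float, space: GenotypeSpace, tol: float = 1e-12) -> float:
    """Continuous (blancmange-like) interpolation of the maximum robustness.

    [log_k n - g_k(k^{{log_k n}-1})/(k-1)] / l for real n >= 1; agrees with
    :func:`rho_max` at integers to floating precision, and equals m/l
    exactly at n = k^m.
    """
    k = space.k
    if not 1 <= n <= space.n_vertices:
        raise ValueError(f"n must lie in [1, {space.n_vertices}], got {n}")
    n_int = int(n)
    exact_power = float(n).is_integer() and k ** _floor_log(n_int, k) == n_int
    if exact_power:
        m = _floor_log(n_int, k)
        return m / space.length  # g_k(1/k) = 0
    m = int(math.floor(math.log(n) / math.log(k)))
    # correct float-log misrounding by direct comparison
    while k ** (m + 1) <= n:
        m += 1
    while k**m > n:
        m -= 1
    x = n / k ** (m + 1)
    log_k_n = math.log(n) / math.log(k)
    return (log_k_n - delange_g(x, k, tol) / (k - 1)) / space.length


def lower_bound_correction(k: int, length: int, n_max: int = 10**6) -> float:
    """The additive correction 2 A_k / ((k-1) l) of the robustness lower bound."""
    A = alphabet_constant(k, n_max).A
    return 2.0 * A / ((k - 1) * length)


def rho_bounds(n: float, space: GenotypeSpace, n_max: int = 10**6) -> tuple[float, float]:
    """(lower, upper) bounds on the maximum robustness at n genotypes.

    upper = log_k(n)/l — identical to the empirical log-linear scaling
    1 + log_k(f)/l with f = n/k^l; lower = upper + 2 A_k/((k-1) l).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    upper = math.log(n) / math.log(space.k) / space.length
    return upper + lower_bound_correction(space.k, space.length, n_max), upper


def rho_min(n: int, space: GenotypeSpace) -> float:
    """Minimum robustness of a fully connected n-genotype neutral component.

    A connected graph on n vertices has at least n - 1 edges (path/star),
    so rho_min = (2/(l(k-1)))(1 - 1/n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return (2.0 / space.degree) * (1.0 - 1.0 / n)


def rho_null(n: int, space: GenotypeSpace) -> float:
    """Random-null expectation rho ~ f = n/k^l (uncorrelated genotypes)."""
    _check_n(n, space)
    return n / space.n_vertices


def percolation_threshold(space: GenotypeSpace) -> float:
    """Frequency 1/(l(k-1)) above which a neutral set should percolate."""
    return 1.0 / space.degree


def giant_component_threshold(k: int) -> float:
    """Frequency 1 - k^{-1/(k-1)} above which components coalesce into one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return 1.0 - k ** (-1.0 / (k - 1))


# ---------------------------------------------------------------------------
# Multi-component splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitInequality:
    """Both sides of the k-tuple sums-of-digits superadditivity inequality."""

    lhs: int
    rhs: int

    @property
    def holds(self) -> bool:
        return self.lhs <= self.rhs


def split_inequality(sizes, k: int) -> SplitInequality:
    """Evaluate sum_i S_k(n_i) + sum_{i<k} (k-i) n_i  vs  S_k(sum n_i).

    ``sizes`` must be k non-negative integers; fewer are zero-padded (the
    zeros occupy the smallest, highest-weight slots and contribute
    nothing).  Unsorted input is sorted ascending with a notice.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sizes = [int(s) for s in sizes]
    if len(sizes) > k:
        raise ValueError(f"at most k={k} sizes allowed, got {len(sizes)}")
    if any(s < 0 for s in sizes):
        raise ValueError("sizes must be non-negative")
    if sizes != sorted(sizes):
        warnings.warn("sizes were not ascending; sorting", stacklevel=2)
        sizes = sorted(sizes)
    sizes = [0] * (k - len(sizes)) + sizes
    lhs = sum(sums_of_digits(s, k) for s in sizes)
    lhs += sum((k - i) * sizes[i - 1] for i in range(1, k))
    rhs = sums_of_digits(sum(sizes), k)
    return SplitInequality(lhs=lhs, rhs=rhs)


@dataclass(frozen=True)
class ComponentSplit:
    """Decomposition of an n-genotype neutral set into component sizes.

    ``proven`` records whether the deviation bound below is rigorously
    established for this split (it is, only when the number of components
    m is at most k).
    """

    sizes: tuple[int, ...]
    k: int

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if not sizes:
            raise ValueError("at least one component size required")
        if any(s < 1 for s in sizes):
            raise ValueError("component sizes must be >= 1")
        object.__setattr__(self, "sizes", tuple(sorted(sizes)))

    @property
    def m(self) -> int:
        return len(self.sizes)

    @property
    def n(self) -> int:
        return sum(self.sizes)

    @property
    def proven(self) -> bool:
        return self.m <= self.k


def multicomponent_deviation_bound(split: ComponentSplit, space: GenotypeSpace) -> float:
    """Lower bound on rho_max(n) - (1/n) sum_i n_i rho(A_i) for a split set.

    Equals (2/(n l (k-1))) sum_{i=1}^{k-1} (k-i) n_i over the ascending
    sizes zero-padded to k entries.  For more than k components the k-1
    smallest sizes are used and the bound is only heuristic
    (``split.proven`` is False).
    """
    k = space.k
    if split.k != k:
        raise ValueError("split alphabet size does not match the genotype space")
    if split.n > space.n_vertices:
        raise ValueError("total size exceeds the genotype space")
    padded = [0] * max(0, k - split.m) + list(split.sizes)
    weighted = sum((k - i) * padded[i - 1] for i in range(1, k))
    return 2.0 * weighted / (split.n * space.degree)


# ---------------------------------------------------------------------------
# Curve export
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ["n", "f", "rho_max", "rho_upper", "rho_lower", "rho_min", "rho_null"]


def robustness_curve(space: GenotypeSpace, n_values=None, n_max_scan: int = 10**6) -> pd.DataFrame:
    """All robustness reference curves at integer n, as a DataFrame.

    Columns: n, f, rho_max (exact, via S_k), rho_upper, rho_lower (the
    sandwich), rho_min (single connected component) and rho_null (= f).
    Defaults to every integer 1..k^l.
    """
    N = space.n_vertices
    if n_values is None:
        n_values = np.arange(1, N + 1, dtype=np.int64)
    else:
        n_values = np.asarray(sorted(set(int(v) for v in n_values)), dtype=np.int64)
        if n_values.size and (n_values[0] < 1 or n_values[-1] > N):
            raise ValueError(f"n values must lie in [1, {N}]")
    if n_values.size and n_values[-1] == N and n_values.size > N // 2:
        S_all = sums_of_digits_range(N, space.k)
        S = S_all[n_values]
    else:
        S = np.array([sums_of_digits(int(v), space.k) for v in n_values], dtype=np.int64)
    nf = n_values.astype(float)
    upper = np.log(nf) / math.log(space.k) / space.length
    corr = lower_bound_correction(space.k, space.length, n_max_scan)
    return pd.DataFrame(
        {
            "n": n_values,
            "f": nf / N,
            "rho_max": 2.0 * S / (nf * space.degree),
            "rho_upper": upper,
            "rho_lower": upper + corr,
            "rho_min": (2.0 / space.degree) * (1.0 - 1.0 / nf),
            "rho_null": nf / N,
        },
        columns=_CURVE_COLUMNS,
    )


def continuous_curve(
    space: GenotypeSpace, num_points: int = 512, tol: float = 1e-12, n_max_scan: int = 10**6
) -> pd.DataFrame:
    """Dense log-spaced grid of the continuous interpolation of rho_max.

    Same columns as :func:`robustness_curve`, with ``n`` real-valued and
    ``rho_max`` taken from the blancmange-like interpolation.
    """
    N = space.n_vertices
    grid = np.geomspace(1.0, float(N), num_points)
    upper = np.log(grid) / math.log(space.k) / space.length
    corr = lower_bound_correction(space.k, space.length, n_max_scan)
    return pd.DataFrame(
        {
            "n": grid,
            "f": grid / N,
            "rho_max": [rho_max_continuous(float(v), space, tol) for v in grid],
            "rho_upper": upper,
            "rho_lower": upper + corr,
            "rho_min": (2.0 / space.degree) * (1.0 - 1.0 / grid),
            "rho_null": grid / N,
        },
        columns=_CURVE_COLUMNS,
    )
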