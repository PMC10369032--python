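"""Sums-of-digits arithmetic and the Delange/Takagi fractal apparatus.

The maximum number of edges of an n-vertex induced subgraph of the Hamming
graph H_{l,k} equals the sums-of-digits function

    S_k(n) = sum_{i=0}^{n-1} s_k(i),

where s_k(i) is the digit sum of i written in base k.  This module provides

* exact integer evaluation of s_k and S_k (a per-digit-position recursion,
  with a naive cumulative-sum oracle available for arrays),
* the Trollope--Delange closed form of S_k(n), built from the fractal
  Delange function D_k (the Takagi/blancmange curve for k = 2),
* the Fourier coefficients of the periodic part of that closed form, which
  involve the Riemann zeta function on the imaginary axis, and
* the alphabet constants A_k of Galkin & Galkina that bound the deviation
  S_k(n)/n - ((k-1)/2) log_k n from below.

Everything downstream (robustness curves and bounds) reduces to these
primitives, so they are kept exact wherever exactness is possible: S_k is
pure integer arithmetic, and the piecewise-linear building block D_{k,0}
is integrated segment-by-segment in closed form rather than by quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import mpmath
import numpy as np

__all__ = [
    "digit_sum",
    "digits",
    "sums_of_digits",
    "sums_of_digits_range",
    "delange_D0",
    "delange_D",
    "delange_g",
    "trollope_delange_S",
    "fourier_coefficient",
    "fourier_c0",
    "fourier_partial_sum",
    "alphabet_constant",
    "AlphabetConstant",
    "FourierCoefficient",
]


def _check_base(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 2:
        raise ValueError(f"base k must be an integer >= 2, got {k!r}")


def digits(i: int, k: int) -> list[int]:
    """Base-k digits of ``i``, most-significant first (``[0]`` for i = 0)."""
    _check_base(k)
    if i < 0:
        raise ValueError("i must be non-negative")
    if i == 0:
        return [0]
    out: list[int] = []
    while i:
        i, r = divmod(i, k)
        out.append(r)
    return out[::-1]


def digit_sum(i: int, k: int) -> int:
    """s_k(i): the sum of the base-k digits of the non-negative integer i."""
    _check_base(k)
    if i < 0:
        raise ValueError("i must be non-negative")
    i = int(i)
    total = 0
    while i:
        i, r = divmod(i, k)
        total += r
    return total


def sums_of_digits(n: int, k: int) -> int:
    """S_k(n) = sum_{i<n} s_k(i), by exact per-digit-position recursion.

    Writing n = q*k + r, the last digit of 0..n-1 cycles through 0..k-1
    q full times plus a partial run 0..r-1, while the higher digits are
    the digits of i // k, each value j < q occurring k times and j = q
    occurring r times:

        S_k(n) = k*S_k(q) + r*s_k(q) + q*k(k-1)/2 + r(r-1)/2.

    Runs in O(log_k n) arithmetic operations on exact integers.
    """
    _check_base(k)
    if n < 0:
        raise ValueError("n must be non-negative")
    n = int(n)
    triangle = k * (k - 1) // 2
    total = 0
    multiplier = 1  # accounts for the k-fold expansion at each level
    while n:
        q, r = divmod(n, k)
        total += multiplier * (r * digit_sum(q, k) + q * triangle + r * (r - 1) // 2)
        n = q
        multiplier *= k
    return total


def sums_of_digits_range(n_max: int, k: int) -> np.ndarray:
    """Array of S_k(0), S_k(1), ..., S_k(n_max) via vectorized cumulation.

    This is the naive definition (cumulative sum of digit sums) executed in
    numpy; it doubles as the independent oracle for :func:`sums_of_digits`
    and powers whole-range scans.  Memory is O(n_max).
    """
    _check_base(k)
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    vals = np.arange(n_max, dtype=np.int64)
    s = np.zeros(n_max, dtype=np.int64)
    while vals.any():
        s += vals % k
        vals //= k
    out = np.zeros(n_max + 1, dtype=np.int64)
    np.cumsum(s, out=out[1:])
    return out


# ---------------------------------------------------------------------------
# Delange / Takagi machinery
# ---------------------------------------------------------------------------


def delange_D0(x, k: int):
    """D_{k,0}(x) = integral_0^x (2k[t] - 2[kt] + k - 1) dt, in closed form.

    The integrand is a step function: on t in [m + j/k, m + (j+1)/k) it
    equals k - 1 - 2j, so the integral over any unit interval vanishes and
    D_{k,0} is 1-periodic with D_{k,0}(m) = 0 at integers.  With y = {x}
    and j = [k y],

        D_{k,0}(x) = j(k - j)/k + (y - j/k)(k - 1 - 2j).

    Accepts a scalar or ndarray; no numeric quadrature is involved.
    """
    _check_base(k)
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("x must be non-negative")
    y = arr - np.floor(arr)
    j = np.minimum(np.floor(k * y), k - 1)
    val = j * (k - j) / k + (y - j / k) * (k - 1 - 2 * j)
    if np.isscalar(x) or arr.ndim == 0:
        return float(val)
    return val


# sup |D_{k,0}| = max_j j(k-j)/k <= k/4, attained mid-period.
def _d0_sup(k: int) -> float:
    return k / 4.0


def delange_D(x, k: int, tol: float = 1e-12):
    """Delange function D_k(x) = sum_{n>=0} D_{k,0}(k^n x) / k^n.

    For k = 2 this is the Takagi (blancmange) function: continuous
    everywhere, differentiable nowhere.  The series is truncated once the
    geometric tail bound sup|D_{k,0}| * k^{-N} * k/(k-1) drops below
    ``tol``.  Accepts a scalar or ndarray.
    """
    _check_base(k)
    if tol <= 0:
        raise ValueError("tol must be positive")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("x must be non-negative")
    sup = _d0_sup(k)
    y = arr - np.floor(arr)  # D_{k,0} is 1-periodic
    total = np.zeros_like(y)
    scale = 1.0
    n = 0
    # tail after the first N terms: sum_{m>=N} sup * k^-m = sup*k^-N*k/(k-1)
    while sup * scale * k / (k - 1) >= tol and n < 200:
        j = np.minimum(np.floor(k * y), k - 1)
        total += scale * (j * (k - j) / k + (y - j / k) * (k - 1 - 2 * j))
        y = k * y
        y -= np.floor(y)
        scale /= k
        n += 1
    if np.isscalar(x) or arr.ndim == 0:
        return float(total)
    return total


def delange_g(x, k: int, tol: float = 1e-12):
    """g_k(x) = (k - 1) log_k x + D_k(x) / x, the periodic profile of S_k.

    Defined for x > 0; the Trollope--Delange formula only ever evaluates it
    on [1/k, 1], where g_k(1/k) = g_k(1) = 0.  Accepts scalar or ndarray.
    """
    _check_base(k)
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("x must be positive")
    val = (k - 1) * np.log(arr) / math.log(k) + delange_D(arr, k, tol) / arr
    if np.isscalar(x) or arr.ndim == 0:
        return float(val)
    return val


def _floor_log(n, k: int) -> int:
    """Exact m with k**m <= n < k**(m+1), by integer comparison.

    Floating log_k(k^m) can land at m - eps and corrupt the fractional part
    {log_k n} exactly where the fractal term matters most, so exact powers
    are detected with integer arithmetic.
    """
    m = max(int(math.log(n) / math.log(k)), 0)
    while k ** (m + 1) <= n:
        m += 1
    while k**m > n:
        m -= 1
    return m


def trollope_delange_S(n: int, k: int, tol: float = 1e-12) -> float:
    """Closed form S_k(n) = (n/2)[(k-1) log_k n - g_k(k^{{log_k n} - 1})].

    Rounding the result to the nearest integer reproduces the exact
    sums-of-digits value.  The fractal argument k^{{log_k n}-1} is computed
    as n / k^{m+1} with m = [log_k n] obtained by integer comparison, which
    keeps it exact in floating point.
    """
    _check_base(k)
    if n < 1:
        raise ValueError("n must be >= 1")
    n = int(n)
    m = _floor_log(n, k)
    x = n / k ** (m + 1)  # = k^{{log_k n} - 1} in [1/k, 1)
    log_k_n = float(m) if k**m == n else math.log(n) / math.log(k)
    return (n / 2.0) * ((k - 1) * log_k_n - delange_g(x, k, tol))


# ---------------------------------------------------------------------------
# Fourier expansion of the periodic part
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourierCoefficient:
    """Coefficient c_n of the Fourier series of x -> g_k(k^{{x}-1})."""

    index: int
    k: int
    value: complex


def fourier_coefficient(index: int, k: int) -> FourierCoefficient:
    """c_n = -(i(k-1)/(n pi)) (1 + i 2 n pi / log k)^{-1} zeta(i 2 n pi / log k).

    Valid for n != 0 (the expression has a pole at n = 0; the mean of the
    periodic function is obtained numerically by :func:`fourier_c0`).  The
    zeta factor is evaluated on the imaginary axis with mpmath.  The overall
    sign is fixed by requiring the synthesis sum_n c_n e^{i 2 pi n x} to
    reproduce g_k(k^{{x}-1}) as evaluated directly; it is verified against
    a numeric Fourier-integral oracle in the test suite.
    """
    _check_base(k)
    if index == 0:
        raise ValueError(
            "c_0 is not covered by the closed form (pole at n=0); "
            "use fourier_c0 for the numeric period mean"
        )
    theta = 2.0 * index * math.pi / math.log(k)
    zeta = complex(mpmath.zeta(1j * theta))
    value = -(1j * (k - 1) / (index * math.pi)) / (1.0 + 1j * theta) * zeta
    return FourierCoefficient(index=index, k=k, value=value)


@lru_cache(maxsize=None)
def fourier_c0(k: int, num_points: int = 1 << 15, tol: float = 1e-12) -> float:
    """Mean of x -> g_k(k^{{x}-1}) over one period, by midpoint rule.

    The function is continuous but nowhere differentiable, so adaptive
    quadrature gains nothing; a dense midpoint rule is accurate to roughly
    O(1/num_points) and entirely adequate for partial-sum reconstruction.
    """
    _check_base(k)
    xs = (np.arange(num_points) + 0.5) / num_points
    return float(np.mean(delange_g(k ** (xs - 1.0), k, tol)))


def fourier_partial_sum(x, k: int, n_terms: int):
    """Partial Fourier sum of g_k(k^{{x}-1}) with |n| <= n_terms.

    Uses the closed-form c_n for n != 0 and the numeric mean for c_0; the
    result is real up to rounding because c_{-n} = conj(c_n).
    """
    _check_base(k)
    if n_terms < 0:
        raise ValueError("n_terms must be non-negative")
    arr = np.asarray(x, dtype=float)
    total = np.full_like(arr, fourier_c0(k), dtype=complex)
    for n in range(1, n_terms + 1):
        c = fourier_coefficient(n, k).value
        phase = np.exp(2j * math.pi * n * arr)
        total += c * phase + np.conj(c) * np.conj(phase)
    if np.isscalar(x) or arr.ndim == 0:
        return float(total.real)
    return total.real


# ---------------------------------------------------------------------------
# Alphabet constants A_k
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlphabetConstant:
    """Lower-bound constant A_k with A_k <= S_k(n)/n - ((k-1)/2) log_k n <= 0.

    ``method`` is "closed_form" for the alphabets whose exact value is
    known (k = 2, 3, 4, 20) and "numeric_scan" otherwise, in which case the
    value is the minimum over n in [1, n_max] — an upper estimate of the
    true infimum.
    """

    k: int
    A: float
    method: str
    n_max: int | None = None


def _closed_form_A(k: int) -> float | None:
    if k == 2:
        return math.log(3) / math.log(4) - 1.0
    if k == 3:
        return math.log(2) / math.log(3) - 1.0
    if k == 4:
        return 0.75 * math.log2(5) - 2.25
    if k == 20:
        return 19.0 * math.log(84.0 / 23.0) / math.log(400.0) - 355.0 / 46.0
    return None


@lru_cache(maxsize=None)
def alphabet_constant(k: int, n_max: int = 10**6) -> AlphabetConstant:
    """A_k: exact closed form for k in {2, 3, 4, 20}, numeric scan otherwise.

    The scan evaluates S_k(n)/n - ((k-1)/2) log_k n on 1 <= n <= n_max
    (vectorized) and takes the minimum; it can only overestimate the true
    infimum, which the ``method`` field flags.
    """
    _check_base(k)
    closed = _closed_form_A(k)
    if closed is not None:
        return AlphabetConstant(k=k, A=closed, method="closed_form")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    S = sums_of_digits_range(n_max, k)
    n = np.arange(1, n_max + 1, dtype=float)
    vals = S[1:] / n - ((k - 1) / 2.0) * np.log(n) / math.log(k)
    return AlphabetConstant(k=k, A=float(vals.min()), method="numeric_scan", n_max=n_max)
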