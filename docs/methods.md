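# Methods

## Model and definitions

Genotypes are sequences of length ℓ over an ordered k-letter alphabet,
identified with the integers 0 … k^ℓ−1 by reading the sequence as a base-k
numeral (position 0 = most significant digit).  The genotype space is the
Hamming graph H_{ℓ,k}; every vertex has degree ℓ(k−1).  A GP map is a
*total* function from vertices to phenotype labels, so neutral sets
partition the graph; the robustness of a phenotype with neutral set G is
ρ = 2|E(G)|/(ℓ(k−1)|V(G)|), the fraction of single-character mutations
that are neutral.  Totality matters: the transition matrix's conservation
law (columns sum to 1) and the full-merge identity (ρ = 1 when all
phenotypes are merged) hold only for complete partitions.  An optional
fill label (e.g. "." for unfolded) completes partial input tables.

## Exact arithmetic for the maximum curve

The maximum robustness at n genotypes is 2 S_k(n)/(n ℓ (k−1)), where
S_k(n) is the sums-of-digits function — the edge count of the bricklayer's
graph on the first n labels, and the edge-isoperimetric optimum.  Three
layers of evaluation are used, each checked against the next:

1. **Exact integers.**  S_k(n) is computed by a per-digit-position
   recursion (O(log_k n) exact integer operations); the naive cumulative
   sum is kept as an independent oracle and as a vectorized whole-range
   table for scans.  All "attains the maximum" decisions compare integer
   edge counts to integer S_k values — no floats, no tolerances.
2. **Closed-form fractal.**  The Trollope–Delange formula
   S_k(n) = (n/2)[(k−1)log_k n − g_k(k^{{log_k n}−1})] is evaluated with
   g_k(x) = (k−1)log_k x + D_k(x)/x and the Delange function
   D_k(x) = Σ_n D_{k,0}(k^n x)/k^n.  The building block D_{k,0} is the
   integral of a step function with breakpoints at multiples of 1/k and is
   integrated segment-by-segment in closed form (it is 1-periodic and
   vanishes at integers); the series is truncated by the geometric tail
   bound sup|D_{k,0}|·k^{−N}·k/(k−1) < tol with sup|D_{k,0}| ≤ k/4.
   Rounding the closed form must reproduce the exact integers — tested for
   all n ≤ 10^4 and k ∈ {2,3,4}.
3. **Floating-point hygiene at powers of k.**  The fractional part
   {log_k n} is the fractal's argument; float logs can land at m − ε for
   n = k^m and corrupt it.  Exact powers are detected by integer
   comparison, and the fractal argument is computed as n/k^{m+1} (exact in
   floating point), so the continuous interpolation touches the exact
   integer points to < 1e−9 and equals m/ℓ exactly at n = k^m.

### Fourier coefficients

The periodic profile x ↦ g_k(k^{{x}−1}) has Fourier coefficients
proportional to ζ(i2nπ/log k)/(n(1 + i2nπ/log k)); the zeta factor is
evaluated on the imaginary axis with mpmath.  The overall sign of the
closed form is fixed by requiring the synthesis Σ c_n e^{i2πnx} to
reproduce the directly evaluated function (a numeric Fourier-integral
oracle pins c_1; partial sums with 200 harmonics then match to ~3e−6).
c_0 is not covered by the closed form (pole at n = 0) and is computed as
the numeric period mean by a 2^15-point midpoint rule — adaptive
quadrature gains nothing on a nowhere-differentiable integrand.

### Alphabet constants

A_k (the infimum of S_k(n)/n − ((k−1)/2)log_k n) has known closed forms
for k ∈ {2, 3, 4, 20}, which are returned exactly.  For other k a
vectorized scan over n ≤ n_max (default 10^6) returns the running minimum,
flagged `numeric_scan`: it is an upper estimate of the true infimum, which
is the conservative direction for the lower robustness bound it feeds.

## Multi-component neutral sets

A neutral set split into components of sizes n_1 ≤ … ≤ n_m cannot reach
the single-component optimum.  The superadditivity property
Σ S_k(n_i) + Σ_{i=1}^{k−1}(k−i)n_i ≤ S_k(Σ n_i) (ascending order,
tuples of exactly k with zero-padding) gives the deviation bound
ρ_max(n) − (1/n)Σ n_i ρ(A_i) ≥ (2/(nℓ(k−1)))Σ_{i=1}^{k−1}(k−i)n_i.
The inequality is proven only for m ≤ k components; for m > k the package
evaluates the same expression on the k−1 smallest sizes and sets
`proven=False` rather than asserting an unproven extension.  The
zero-padding convention (S_k(0) = 0, weight × 0 = 0) keeps both sides
consistent when m < k.

## Transition matrices and coarse-graining

φ[t, s] = |E(G_s, G_t)|/(ℓ(k−1)|V(G_s)|) is the probability that a random
mutation of a random phenotype-s genotype lands on t; the diagonal carries
ρ_s with its factor 2 (internal edges are seen from both endpoints).  Edge
counts between phenotype classes are accumulated by streaming vectorized
per-position edge blocks — the full edge list (k^ℓ ℓ(k−1)/2 entries) is
never materialized.  With the φ_ss = ρ_s convention, coarse-graining is a
single frequency-weighted average over group pairs, applied uniformly to
diagonal and off-diagonal entries; it is associative (two-step = composed
one-step) and computed identically whether applied to the matrix or by
relabelling the map — the two routes are cross-checked in tests.
Phenotype order everywhere is descending neutral-set size with
lexicographic tie-break, so all outputs are deterministic.

For a pairwise merge in the high-robustness regime, writing
ρ_i = 1 + log_k(f_i)/ℓ − Δ_i, the merged robustness is linear in φ_qp, and
requiring it to stay within [min Δ, max Δ] of the asymptotic line at the
merged frequency yields the critical thresholds

    φ_* = [F log_k F − f_p log_k f_p − f_q log_k f_q
           + ℓ(f_p Δ_p + f_q Δ_q − F Δ_*)] / (2 ℓ f_p),

F = f_p + f_q, with Δ_* = min(Δ_p, Δ_q) for the upper and max for the
lower threshold (equal Δ collapses them).  These closed forms were derived
by solving the linear merged-robustness approximation directly; a
substitution oracle in the test suite verifies that the merged robustness
evaluated at each threshold reproduces its target level to machine
precision.  Δ values measured from data are clipped at 0 with a warning:
for very small neutral sets the asymptotic line can dip below the exact
maximum, and negative displacements are outside the regime the thresholds
assume.  Base-k logarithms are used throughout.

## Synthetic map generators

Two generators define the study conditions for all map-level tests:

* **random null** — genotypes assigned to phenotypes uniformly at random
  with neutral-set sizes held fixed (a seeded permutation partition).
  This is the classical uncorrelated-assignment null; under it the exact
  expected robustness of an n-genotype phenotype is hypergeometric,
  E[ρ] = (n−1)/(N−1) with N = k^ℓ, which equals the frequency f = n/N up
  to the finite-size correction (1−f)/(N−1).  Tests of the null scaling
  ρ ≈ f therefore compare Monte-Carlo means to the exact expectation at
  Monte-Carlo precision and to f at the finite-size-correction scale; on
  the 64-vertex spaces used, that correction is resolvable, so treating
  ρ = f as exact would be wrong at achievable precision.
* **bricklayer-packed** — phenotypes occupy consecutive integer-label
  blocks, so the first phenotype attains ρ_max by construction and later
  blocks provide near-extremal but non-optimal sets.

What these generators emulate is the combinatorial structure the theory
addresses: sizes, connectivity, edge counts.  What they do not emulate is
the correlation structure of physical folding maps (real RNA/protein
neutral sets are far more robust than the null and can attain the
bricklayer bound at much larger sizes); passing tests therefore validate
the mathematics and the pipeline, not any claim about a particular
biophysical system.

## Problem sizes and numerical choices

Exhaustive oracles run where exhaustion is exact and cheap: brute-force
subset enumeration on H_{3,2}, H_{4,2}, H_{2,3} (≤ 2^16 subsets, refused
above a configurable budget rather than silently sampled), the
superadditivity inequality on all ascending tuples with Σ n_i ≤ 200 for
k ∈ {2,3,4}, sandwich bounds on every integer n for k ∈ {2,3,4},
ℓ ∈ 4…10, and the Trollope–Delange round-trip for n ≤ 10^4.  Monte-Carlo
checks use 200 seeded replicates on 64-vertex spaces.  Default series
tolerance is 1e−12 (1e−10 where only integer rounding is needed).  The
CLI `curve` command enumerates every integer n up to 2^16 vertices and
switches to a log-spaced integer subsample above that; the full range
remains available through the API.

## Known limitations

* A_k outside {2, 3, 4, 20} is a scan estimate, not the exact constant.
* The m > k branch of the multi-component bound is a flagged heuristic.
* The merge thresholds assume the high-robustness asymptotic regime;
  applied to low-robustness (e.g. random-null) phenotypes they remain
  well-defined but their "keeps the merge near the optimal line" reading
  weakens.
* Folding engines are out of scope: the package consumes already-folded
  GP maps (or generates synthetic ones); it does not predict phenotypes.
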