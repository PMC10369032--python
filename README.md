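# gprobust

Exact mutational-robustness bounds for genotype–phenotype (GP) maps.

## The problem

A GP map sends every sequence of length ℓ over a k-letter alphabet (RNA:
k = 4, proteins: k = 20, binary models: k = 2) to a discrete phenotype.
The genotypes of one phenotype — its *neutral set* — form an induced
subgraph G_p of the Hamming graph H_{ℓ,k}, whose vertices are all k^ℓ
sequences and whose edges join sequences differing at one position.  The
phenotype's mutational robustness is the fraction of single-character
mutations that preserve the phenotype,

    ρ_p = 2|E(G_p)| / (ℓ(k−1)|V(G_p)|),        0 ≤ ρ_p ≤ 1.

How robust can a phenotype possibly be, given only its neutral-set size n?
The answer is an edge-isoperimetry result from coding theory: the maximum
is attained by *bricklayer's graphs* — the induced subgraphs on the first
n integer vertex labels — and its value is governed by the number-theoretic
sums-of-digits function S_k(n) = Σ_{i<n} s_k(i):

    ρ_max(n) = 2 S_k(n) / (n ℓ (k−1)).

S_k(n) has an exact fractal closed form (Trollope–Delange) built from the
Delange function D_k — the Takagi/blancmange curve when k = 2 — and is
sandwiched by

    log_k(n)/ℓ + 2A_k/((k−1)ℓ)  ≤  ρ_max(n)  ≤  log_k(n)/ℓ,

where A_k is an alphabet-only constant (A_4 ≈ −0.5086 for nucleotides,
A_20 ≈ −3.6097 for amino acids).  The upper line is exactly the empirical
log-linear robustness scaling ρ ≈ 1 + log_k(f)/ℓ seen across biological
GP maps.

`gprobust` computes these curves exactly, analyzes complete GP maps
against them (neutral sets, neutral components, phenotype transition
matrices, multi-component deviation bounds), and coarse-grains phenotypes
— merging neutral sets, with closed-form critical transition probabilities
that decide whether a merge keeps the compound phenotype near the optimal
robustness line.

It is primarily a library; a thin `gprobust` command-line tool exposes the
same computations (`curve`, `analyze`, `coarsegrain`, `fixtures`,
`thresholds`) for shell use.

## Worked example

```python
from gprobust import (GenotypeSpace, generate_bricklayer_packed,
                      phenotype_stats, rho_max)

space = GenotypeSpace(k=2, length=3)              # the 8-vertex cube
gp = generate_bricklayer_packed(space, [5, 3], labels=["A", "B"])
for st in phenotype_stats(gp):
    print(st.label, st.n, st.edge_count, round(st.rho, 4),
          st.components[0].attains_max)
```

prints

```
A 5 5 0.6667 True
B 3 2 0.4444 True
```

Phenotype A occupies vertex labels 0–4, a bricklayer's graph: its 5 edges
equal S_2(5) = 5, so ρ_A = 2·5/(5·3·1) = 2/3 attains ρ_max(5) exactly —
the same 5-vertex optimum as the densest possible neutral network on the
cube.  The `examples/` directory holds one short narrative script per
capability (curves, GP-map analysis, coarse-graining, merge thresholds);
each prints its numbers with a sentence on what they mean.

A shell session for the same analysis:

```sh
gprobust fixtures --kind bricklayer --k 2 --length 3 --sizes 5,3 --out map.tsv
gprobust analyze map.tsv --out-prefix out     # out.stats.csv, out.matrix.csv, out.deviation.csv
gprobust curve --k 2 --length 6 --out curve.csv
```

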