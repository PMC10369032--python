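"""Phenotype coarse-graining on a random-null genotype-phenotype map.

Generates a complete map on the 16-vertex Hamming graph H_{4,2} with three
phenotypes (neutral-set sizes 6, 5, 5) under the random null model, builds
the transition matrix (robustness on the diagonal), merges two phenotypes,
and finally merges all of them — which must give robustness exactly 1,
since every mutation then stays inside the union.
"""

from gprobust import (
    GenotypeSpace,
    Partition,
    coarse_grain,
    generate_random_null,
    transition_matrix,
)

space = GenotypeSpace(k=2, length=4)
gp = generate_random_null(space, [6, 5, 5], seed=1)
tm = transition_matrix(gp)

print("transition matrix phi[t, s] (columns = source phenotype, diagonal = rho):")
print(tm.to_dataframe().round(4).to_string())
print("column sums:", tm.phi.sum(axis=0).round(12))

merged_two = coarse_grain(tm, Partition({"P1": "P1+P2", "P2": "P1+P2", "P3": "P3"}))
print("\nafter merging P1 and P2:")
print(merged_two.to_dataframe().round(4).to_string())

merged_all = coarse_grain(tm, Partition.all_to_one(tm.labels))
print(f"\nfull merge of all phenotypes: rho = {merged_all.phi[0, 0]:.12f}")
print(
    "\nMerged frequencies add; merged transition probabilities are the\n"
    "frequency-weighted averages of their parts, and cross-transitions\n"
    "between merged phenotypes become robustness, so the full merge of a\n"
    "complete map always has rho = 1."
)
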