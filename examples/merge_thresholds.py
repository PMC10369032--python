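"""Critical transition probabilities for merging two robust phenotypes.

Two phenotypes sitting Delta_p and Delta_q below the asymptotic optimal
robustness line rho = 1 + log_k(f)/l stay within [min Delta, max Delta] of
that line after merging only if their transition probability phi_qp lies
between two closed-form critical values.  This script prints those bounds
for a nucleotide-like space (k = 4, l = 12), verifies them by substitution,
then classifies every phenotype pair of a generated map.
"""

from gprobust import (
    GenotypeSpace,
    classify_pairs,
    critical_phi_bounds,
    generate_random_null,
    merged_rho_asymptotic,
    transition_matrix,
)

space = GenotypeSpace(k=4, length=12)
f_p, f_q = 0.1, 0.05          # beta = f_q/f_p = 0.5
d_p, d_q = 0.10, 0.02         # displacements below the optimal line
lo, hi = critical_phi_bounds(f_p, f_q, d_p, d_q, space)
print(f"critical bounds on phi_qp: lower = {lo:.6f}, upper = {hi:.6f}")
print(f"  merged rho at phi_lower: {merged_rho_asymptotic(f_p, f_q, d_p, d_q, lo, space):.6f}")
print(f"  merged rho at phi_upper: {merged_rho_asymptotic(f_p, f_q, d_p, d_q, hi, space):.6f}")

small = GenotypeSpace(k=2, length=6)
gp = generate_random_null(small, [28, 16, 12, 8], seed=11)
pairs = classify_pairs(transition_matrix(gp), small)
print("\npair classification on a random-null map over H_{6,2}:")
print(pairs[["p", "q", "beta", "phi_qp", "phi_lower", "phi_upper", "class"]]
      .round(4).to_string(index=False))
print("\ncounts:", pairs["class"].value_counts().to_dict())
print(
    "\n'undershoot' pairs are too weakly connected: merging them would drop\n"
    "the compound phenotype further below the optimal robustness line than\n"
    "either member; 'overshoot' pairs are so densely connected that the\n"
    "merge moves closer to the line.  Random-null maps tend to overshoot\n"
    "or sit within the bounds, because phi_ts ~ f_t is large relative to\n"
    "their (low) robustness."
)
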