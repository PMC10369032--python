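"""Neutral-set analysis of a small genotype-phenotype map.

Packs the 8-vertex binary cube H_{3,2} into two phenotypes, the first
occupying the first five integer labels (a bricklayer's graph), and checks
each phenotype's robustness and neutral components against the exact
bricklayer maximum and the connectivity minimum.
"""

from gprobust import (
    GenotypeSpace,
    deviation_table,
    generate_bricklayer_packed,
    phenotype_stats,
    rho_max,
)

space = GenotypeSpace(k=2, length=3)
gp = generate_bricklayer_packed(space, [5, 3], labels=["A", "B"])

for st in phenotype_stats(gp):
    flags = ", ".join(
        f"size={c.size} edges={c.edge_count} attains_max={c.attains_max}"
        for c in st.components
    )
    print(
        f"phenotype {st.label}: n={st.n} f={st.f:.3f} rho={st.rho:.4f} "
        f"(rho_max at this n: {rho_max(st.n, space):.4f}) | components: {flags}"
    )

print()
print(deviation_table(gp).to_string(index=False))
print()
print(
    "Phenotype A is a bricklayer's graph: its 5 edges equal S_2(5) = 5, so\n"
    "rho = 2/3 attains the maximum exactly.  The deviation table compares\n"
    "rho_max(n) minus the component-weighted robustness (lhs) against the\n"
    "multi-component lower bound (rhs); 'proven' marks phenotypes with at\n"
    "most k components, where the inequality is rigorous."
)
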