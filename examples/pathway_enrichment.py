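"""Hypergeometric over-representation of a target set in pathway gene sets.

Builds a toy background of 60 genes and two pathways, queries with a gene
set that overlaps the first pathway heavily, and prints the exact
hypergeometric p values with Bonferroni correction over the tested family.
"""

from mirdegree import hypergeometric_enrichment

background = [f"G{i:02d}" for i in range(60)]
gene_sets = {
    "cell-cycle": set(background[:12]),
    "adhesion": set(background[40:55]),
}
query = set(background[:8]) | {"G45", "G50"}

for r in hypergeometric_enrichment(query, gene_sets, background, alpha=0.05):
    print(f"{r.pathway_id:11s} overlap {r.overlap:2d}/{r.pathway_size:2d} "
          f"p_raw={r.p_raw:.2e} p_bonferroni={r.p_bonferroni:.2e} "
          f"significant={r.significant}")
# p_raw is P(X >= overlap) for drawing |query| genes from the background;
# the Bonferroni multiplier is 2 (both pathways intersect the background).
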