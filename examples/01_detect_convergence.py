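"""Detect convergent amino-acid substitutions in a synthetic study.

Generates a 20-gene, 17-taxon study with 10 foreground and 3 background
convergent sites planted among neutrally evolving columns, scans every
gene with the conservative-site caller, and compares foreground vs
background totals with the symmetric chi-square test.
"""

from ccsconv import aggregate, generate_study, scan_gene

study = generate_study(
    n_genes=20, gene_length=300, alpha=0.8,
    planted_fg=10, planted_bg=3, seed=42,
)
gene_calls = {g.gene_id: scan_gene(g, study.design) for g in study.genes}
report = aggregate(gene_calls)

print(f"foreground convergent substitutions: {report.foreground_count}")
print(f"background convergent substitutions: {report.background_count}")
print(f"genes with foreground calls:         {report.genes_with_foreground}")
print(f"genes with >=2 foreground sites:     {report.multi_site_genes}")
print(f"chi2 = {report.chi2_stat:.3f}, p = {report.p_value:.4g}")
print()
for gene_id, calls in sorted(gene_calls.items()):
    for c in calls:
        print(f"  {gene_id} {c.substitution_label:>6} ({c.direction}, "
              f"{len(c.supporting_taxa)} supporting taxa)")
print()
print("Foreground counts above background with small p indicate an excess")
print("of parallel identical substitutions in the two foreground clusters;")
print("labels like D401E give ancestral state, column, derived state.")
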