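"""Simulate a two-population pool-seq dataset and run the FST scan.

Generates a small genome (2 scaffolds, ~2e4 SNPs at background F = 0.05,
sequencing depth 100x over pools of 50 individuals), calls biallelic
SNPs, and computes FST at the SNP, gene (exonic) and gene-plus-5kb-flank
level.  The printed means should all sit near the per-SNP expectation of
the estimator at this depth — a little below the simulated F of 0.05
because read sampling inflates within-pool heterozygosity.
"""

import poolscan as ps

config = ps.SimulationConfig(seed=42)
annotation = ps.simulate_annotation(config)
sites, truth = ps.simulate_divergence(config, annotation=annotation)

snp_df, rejections = ps.call_snps(sites)
snp_df = ps.add_fst_columns(snp_df)
gene_df = ps.gene_fst_table(
    list(annotation.genes), snp_df, flank=5000,
    scaffold_lengths=config.scaffold_lengths,
)

print(f"sites simulated:   {len(sites)}  (rejected: {rejections})")
print(f"SNPs accepted:     {len(snp_df)}")
print(f"mean SNP FST:      {snp_df['fst'].mean():.4f}   (simulated F = {config.background_F})")
genes_with_data = gene_df["fst_gene"].dropna()
print(f"genes with FST:    {len(genes_with_data)} of {len(gene_df)}")
print(f"mean gene FST:     {genes_with_data.mean():.4f}")
print(f"mean flanking FST: {gene_df['fst_flanking_combined'].dropna().mean():.4f}")
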