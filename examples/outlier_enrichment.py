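"""Select genome-scan outliers and test functional-term enrichment.

Plants 10 genes at F = 0.3 on an F = 0.05 background, selects genes
above the genome-wide 97.5th percentile of FST, and runs one-sided
hypergeometric enrichment over a random term map that also contains a
custom term holding exactly the planted candidate genes.  The candidate
term should surface at the top of the enrichment table with a tiny
BH-adjusted p — the planted genes ARE the outliers.
"""

import poolscan as ps

config = ps.SimulationConfig(seed=3, candidate_F=0.3, n_candidates=10)
annotation = ps.simulate_annotation(config)
sites, _ = ps.simulate_divergence(config, annotation=annotation)

snp_df = ps.add_fst_columns(ps.call_snps(sites)[0])
gene_df = ps.gene_fst_table(list(annotation.genes), snp_df,
                            scaffold_lengths=config.scaffold_lengths)
values = gene_df.set_index("gene_id")["fst_gene"].dropna()

selection = ps.select_outliers(values, percentile=97.5)
print(f"threshold (97.5th pct): {selection.threshold:.4f}")
print(f"outlier genes:          {len(selection.outlier_ids)} of {len(values)}")

amap = annotation.term_map.restrict(values.index, min_term_size=5)
enrichment = ps.fisher_enrichment(selection.outlier_ids, amap, values.index)
top = enrichment.head(3)[["term_id", "n_outlier_in_term", "n_term", "p_value", "bh_adjusted_p"]]
print("top enriched terms (the candidate term should lead):")
print(top.to_string(index=False))
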