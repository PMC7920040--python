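"""Immune-assay indices on a synthetic larval cohort.

Simulates hemocyte counts for two populations (the northern one given a
higher phagocytosis propensity) and computes: total hemocyte
concentration from hemocytometer counts, the overall phagocytic index
per larva, and the specific phagocytic index (per-cell-type propensity).
Group means should echo the planted contrast: north above south on
every propensity, concentrations around 14,000 cells/µl.
"""

import poolscan as ps
from poolscan.phenotype import thc_table

cohort = ps.CohortConfig(seed=5)
cells, hemocytometer, truth = ps.simulate_cohort(cohort)

conc = thc_table(hemocytometer)["cells_per_ul"]
print(f"total hemocyte count: mean {conc.mean():,.0f} cells/µl (SD {conc.std(ddof=1):,.0f})")

summary = ps.assay_summary(cells)
overall = summary[summary["index"] == "phagocytic_index"]
for _, row in overall.iterrows():
    print(f"phagocytic index  {row['population']:>5} {row['sex']}: "
          f"{row['mean']:.3f} (SD {row['sd']:.3f}, n={row['n']})")

print("specific phagocytic index, granulocytes (planted in parentheses):")
specific = summary[summary["index"] == "specific_index_granulocyte"]
for _, row in specific.iterrows():
    planted = truth["propensities"][(row["population"], row["sex"], "granulocyte")]
    print(f"  {row['population']:>5} {row['sex']}: {row['mean']:.3f}  ({planted:.2f})")
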