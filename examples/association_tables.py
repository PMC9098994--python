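"""Contingency-table association statistics, as in a clinicopathology table.

Recomputes the LOH x mutation association from published patient counts
(odds ratio, Fisher exact and corrected chi-square p), then runs the
hotspot-panel LOH association with FDR adjustment on a synthetic cohort.
"""

import numpy as np

from lohcna import (
    CohortSpec,
    ContingencyTable,
    chi_square,
    cohort_gene_matrix,
    fisher_exact_2x2,
    generate_cohort,
)
from lohcna.gene_level import HOTSPOT_PANEL, hotspot_association, hotspot_summary

# KRAS LOH (rows) x KRAS mutation (columns) patient counts
table = ContingencyTable(
    np.array([[16, 45], [69, 99]]), ("loh", "no_loh"), ("mut", "wt")
)
fisher = fisher_exact_2x2(table)
chi2 = chi_square(table, continuity_correction=True)
print("KRAS LOH x KRAS mutation")
print(f"  odds ratio          {fisher.estimate:.2f}   (<1: LOH and mutation co-occur less than expected)")
print(f"  Fisher exact p      {fisher.p_value:.4f}")
print(f"  corrected chi2 p    {chi2.p_value:.4f}")
print()

cohort = generate_cohort(CohortSpec(n_samples=200), seed=5)
panel = [g for g in cohort.genome.genes if g.gene_symbol in HOTSPOT_PANEL]
matrix = cohort_gene_matrix(cohort.profiles, panel)
kras_loh = {s: bool(c is not None and c.loh) for s, c in matrix.loc["KRAS"].items()}

summary = hotspot_summary(matrix, kras_loh=kras_loh)
assoc = hotspot_association(matrix, kras_loh)
print("hotspot panel, synthetic cohort (percent of samples):")
print(summary.round(1).to_string())
print()
print("LOH association with KRAS LOH (chi-square / Fisher, BH-adjusted):")
print(assoc.round(4).to_string())
print()
print("Gain/loss/LOH percentages summarize the cohort; the adjusted p-values")
print("flag panel genes whose LOH co-occurs with KRAS LOH beyond chance.")
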