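"""Survival stratification by KRAS LOH and mutation status.

Fits univariate and age-adjusted Cox models for KRAS LOH, scans potential
confounders in bivariate models, and reports Kaplan-Meier medians for the
four LOH x mutation strata.
"""

import pandas as pd

from lohcna import (
    CohortSpec,
    bivariate_scan,
    cohort_gene_matrix,
    cox_fit,
    generate_cohort,
    genome_instability_index,
    stratified_km_report,
)

cohort = generate_cohort(CohortSpec(n_samples=800), seed=29)
kras_calls = cohort_gene_matrix(
    cohort.profiles, [g for g in cohort.genome.genes if g.gene_symbol == "KRAS"]
).loc["KRAS"]
loh = {s: int(c is not None and c.loh) for s, c in kras_calls.items()}
gii = {p.sample_id: genome_instability_index(p, cohort.genome.probes).value
       for p in cohort.profiles}

df = pd.DataFrame(
    {
        "time": [r.os_time for r in cohort.clinical],
        "event": [r.os_event for r in cohort.clinical],
        "loh": [loh[r.sample_id] for r in cohort.clinical],
        "age": [r.age for r in cohort.clinical],
        "stage2plus": [int(r.stage in ("II", "III")) for r in cohort.clinical],
        "gii": [gii[r.sample_id] for r in cohort.clinical],
        "mut": [int(bool(r.kras_mut)) for r in cohort.clinical],
    }
)

uni = cox_fit(df, ["loh"])
multi = cox_fit(df, ["loh", "age", "stage2plus"])
print("overall survival, Cox proportional hazards:")
row = uni.summary.loc["loh"]
print(f"  KRAS LOH univariate:   HR {row.hr:.2f} ({row.ci_lower:.2f}-{row.ci_upper:.2f}), p = {row.p_value:.3f}")
row = multi.summary.loc["loh"]
print(f"  adjusted (age, stage): HR {row.hr:.2f} ({row.ci_lower:.2f}-{row.ci_upper:.2f}), p = {row.p_value:.3f}")

scan = bivariate_scan(df, "loh", ["gii", "mut"])
print("\nbivariate scan (KRAS LOH fixed, one covariate at a time):")
print(scan[["hr", "ci_lower", "ci_upper", "p_value"]].round(3).to_string())

strata = [
    ("mut+loh" if m and l else "mut" if m else "loh" if l else "wt")
    for m, l in zip(df["mut"], df["loh"])
]
curves, global_p, pairwise = stratified_km_report(df.time.values, df.event.values, strata)
print("\nKaplan-Meier medians by KRAS mutation x LOH stratum (months):")
for label, curve in curves.items():
    print(f"  {label:8s} {curve.median:6.1f}")
print(f"global log-rank p = {global_p:.3f}")
print()
print("With the planted hazard ratio of 0.65 for LOH, the LOH strata show")
print("longer median survival; the bivariate scan shows the LOH effect is")
print("stable when genomic instability or mutation status is adjusted for.")
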