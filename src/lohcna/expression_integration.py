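"""Copy-number / expression integration and nearest-centroid subtyping.

Three analyses: (1) per-gene Pearson correlation between copy number and
log2 mRNA expression, with BH adjustment across tested genes and selection
at r and q thresholds; (2) differential expression between LOH-defined
sample groups (Welch t per gene, BH across genes), with set intersection
across cohorts; (3) assignment of lung-adenocarcinoma expression subtypes
(TRU / PP / PI) to the nearest signature centroid by Pearson correlation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import bh_adjust

__all__ = [
    "SUBTYPES",
    "cn_expression_correlation",
    "select_correlated",
    "differential_expression",
    "intersect_cohort_de",
    "assign_subtypes",
]

SUBTYPES = ("TRU", "PP", "PI")


def cn_expression_correlation(cn_matrix: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pearson correlation of copy number with expression.

    Genes are intersected by symbol and samples by id; genes whose copy
    number (or expression) does not vary are excluded with a reason code.
    Returns columns r, p_value, q_value, n_samples, excluded_reason.
    """
    samples = cn_matrix.columns.intersection(expr.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    genes = cn_matrix.index.intersection(expr.index)
    rows = {}
    pvals, tested = [], []
    for gene in genes:
        cn = cn_matrix.loc[gene, samples].to_numpy(dtype=float)
        ex = expr.loc[gene, samples].to_numpy(dtype=float)
        keep = np.isfinite(cn) & np.isfinite(ex)
        cn, ex = cn[keep], ex[keep]
        n = int(keep.sum())
        if n < 3:
            rows[gene] = (np.nan, np.nan, n, "insufficient_samples")
            continue
        if np.ptp(cn) == 0:
            rows[gene] = (np.nan, np.nan, n, "zero variance")
            continue
        if np.ptp(ex) == 0:
            rows[gene] = (np.nan, np.nan, n, "constant expression")
            continue
        r, p = stats.pearsonr(cn, ex)
        rows[gene] = (float(r), float(p), n, "")
        pvals.append(max(float(p), np.nextafter(0, 1)))  # exact fits underflow to 0
        tested.append(gene)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["r", "p_value", "n_samples", "excluded_reason"]
    )
    out.index.name = "gene"
    out["q_value"] = np.nan
    if pvals:
        out.loc[tested, "q_value"] = bh_adjust(pvals)
    return out[["r", "p_value", "q_value", "n_samples", "excluded_reason"]]


def select_correlated(results: pd.DataFrame, r_min: float = 0.4, q_max: float = 0.05) -> set[str]:
    """Genes with r strictly above r_min and q strictly below q_max."""
    if results.empty:
        return set()
    keep = (results.r > r_min) & (results.q_value < q_max)
    return set(results.index[keep.fillna(False)])


def differential_expression(expr: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene Welch t-test between 'loh' and 'no_loh' sample groups.

    ``groups`` maps sample id to 'loh' / 'no_loh'. Effect is
    mean(loh) - mean(no_loh) on the log2 scale. Returns columns effect,
    p_value, q_value.
    """
    loh = [s for s in expr.columns if groups.get(s) == "loh"]
    ref = [s for s in expr.columns if groups.get(s) == "no_loh"]
    if len(loh) < 2 or len(ref) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = expr[loh].to_numpy(dtype=float)
    b = expr[ref].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # a gene constant in both groups has an undefined t; treat as no evidence
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame(
        {
            "effect": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p,
            "q_value": bh_adjust(np.clip(p, np.nextafter(0, 1), 1.0)),
        },
        index=expr.index,
    )
    out.index.name = "gene"
    return out


def significant_genes(de: pd.DataFrame, q_max: float = 0.05) -> set[str]:
    """Genes significant after FDR adjustment."""
    return set(de.index[de.q_value < q_max])


def intersect_cohort_de(de_a: set[str], de_b: set[str]) -> set[str]:
    """Genes differentially expressed in both cohorts."""
    return set(de_a) & set(de_b)


def assign_subtypes(
    expr: pd.DataFrame,
    centroids: pd.DataFrame,
    metric: str = "pearson",
    min_gene_coverage: float = 0.5,
) -> pd.DataFrame:
    """Assign each sample to the nearest expression-subtype centroid.

    ``centroids`` is signature genes x subtypes. Expression is
    median-centered per gene over the cohort before comparison. The default
    distance is 1 - Pearson correlation; 'spearman' and 'euclidean' are
    options. Ties go to the earlier subtype in column order and are flagged.

    Returns a DataFrame with columns subtype, score (correlation with the
    winning centroid, or negative distance for euclidean), ambiguous.
    """
    shared = centroids.index.intersection(expr.index)
    coverage = len(shared) / len(centroids.index)
    if coverage < min_gene_coverage:
        missing = sorted(centroids.index.difference(expr.index))
        raise ValueError(
            f"only {coverage:.0%} of centroid genes present "
            f"(floor {min_gene_coverage:.0%}); missing: {missing[:20]}"
        )
    sub = expr.loc[shared]
    centered = sub.sub(sub.median(axis=1), axis=0)
    cent = centroids.loc[shared]
    labels, scores, ambiguous = [], [], []
    for sample in centered.columns:
        vec = centered[sample].to_numpy(dtype=float)
        sims = []
        for subtype in cent.columns:
            c = cent[subtype].to_numpy(dtype=float)
            if metric == "pearson":
                sims.append(stats.pearsonr(vec, c)[0])
            elif metric == "spearman":
                sims.append(stats.spearmanr(vec, c)[0])
            elif metric == "euclidean":
                sims.append(-float(np.linalg.norm(vec - c)))
            else:
                raise ValueError(f"unknown metric {metric!r}")
        sims = np.asarray(sims)
        best = int(np.argmax(sims))
        labels.append(cent.columns[best])
        scores.append(float(sims[best]))
        ambiguous.append(bool(np.sum(np.isclose(sims, sims[best], atol=1e-12)) > 1))
    return pd.DataFrame(
        {"subtype": labels, "score": scores, "ambiguous": ambiguous},
        index=pd.Index(centered.columns, name="sample"),
    )
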