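"""Projection of segment calls onto genes and hotspot-panel summaries.

A gene takes the call of the overlapping segment with the largest base-pair
overlap. Ties are broken by the more extreme |adjusted copy number|, then by
LOH present, then by the leftmost segment, making the assignment a
deterministic function of the profile. Genes overlapping no segment get no
call (``None``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .association_stats import bh_adjust, build_contingency, chi_square, fisher_exact_2x2
from .cna_core import AberrationState, SegmentCall, call_profile
from .io_formats import GeneAnnotation, SegmentProfile

__all__ = [
    "HOTSPOT_PANEL",
    "GeneAberrationCall",
    "gene_call",
    "cohort_gene_matrix",
    "matrix_field",
    "hotspot_summary",
    "hotspot_association",
]

#: Recurrently altered lung-adenocarcinoma genes summarized by default.
HOTSPOT_PANEL = (
    "KRAS", "EGFR", "TP53", "ALK", "ERBB2", "BRAF", "MET",
    "RET", "ROS1", "NTRK1", "NTRK2", "NTRK3", "STK11", "PIK3CA",
)


@dataclass(frozen=True)
class GeneAberrationCall:
    gene_symbol: str
    sample_id: str
    adjusted_cn: int
    state: AberrationState
    loh: bool
    copy_neutral_loh: bool
    covered_fraction: float


def gene_call(
    profile: SegmentProfile,
    gene: GeneAnnotation,
    calls: Optional[Sequence[SegmentCall]] = None,
) -> Optional[GeneAberrationCall]:
    """Assign a segment call to a gene, or ``None`` if nothing overlaps it.

    ``calls`` may be passed to avoid re-calling the profile's segments when
    mapping many genes of one sample.
    """
    if calls is None:
        calls = call_profile(profile)
    best: Optional[tuple] = None
    for call in calls:
        seg = call.segment
        if seg.chrom != gene.chrom:
            continue
        overlap = min(seg.end, gene.tx_end) - max(seg.start, gene.tx_start) + 1
        if overlap <= 0:
            continue
        key = (overlap, abs(call.adjusted_cn), call.loh, -seg.start)
        if best is None or key > best[0]:
            best = (key, overlap, call)
    if best is None:
        return None
    _, overlap, call = best
    return GeneAberrationCall(
        gene_symbol=gene.gene_symbol,
        sample_id=profile.sample_id,
        adjusted_cn=call.adjusted_cn,
        state=call.state,
        loh=call.loh,
        copy_neutral_loh=call.copy_neutral_loh,
        covered_fraction=overlap / gene.length,
    )


def cohort_gene_matrix(
    profiles: Sequence[SegmentProfile], genes: Sequence[GeneAnnotation]
) -> pd.DataFrame:
    """Genes x samples DataFrame of :class:`GeneAberrationCall` (or ``None``)."""
    data = {}
    for profile in profiles:
        calls = call_profile(profile)
        data[profile.sample_id] = [gene_call(profile, g, calls) for g in genes]
    return pd.DataFrame(data, index=[g.gene_symbol for g in genes])


def matrix_field(matrix: pd.DataFrame, field: str) -> pd.DataFrame:
    """Extract one attribute of every call into a plain DataFrame (NaN for no call)."""
    return matrix.map(lambda c: getattr(c, field) if c is not None else None)


def hotspot_summary(
    matrix: pd.DataFrame,
    panel: Sequence[str] = HOTSPOT_PANEL,
    kras_loh: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Cohort-wide gain/loss/LOH percentages per panel gene.

    When per-sample KRAS-LOH flags are given, a fourth column reports each
    gene's LOH percentage within the KRAS-LOH-positive subgroup.
    """
    missing = [g for g in panel if g not in matrix.index]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    if kras_loh is None and "KRAS" in matrix.index:
        kras_loh = {
            s: bool(c is not None and c.loh) for s, c in matrix.loc["KRAS"].items()
        }
    rows = []
    for gene in panel:
        calls = [c for c in matrix.loc[gene] if c is not None]
        n = len(calls)
        row = {
            "gain_pct": 100 * sum(c.state is AberrationState.GAIN for c in calls) / n if n else 0.0,
            "loss_pct": 100 * sum(c.state is AberrationState.LOSS for c in calls) / n if n else 0.0,
            "loh_pct": 100 * sum(c.loh for c in calls) / n if n else 0.0,
        }
        if kras_loh is not None:
            sub = [
                c for c in calls if kras_loh.get(c.sample_id, False)
            ]
            row["loh_pct_within_kras_loh"] = (
                100 * sum(c.loh for c in sub) / len(sub) if sub else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(panel, name="gene"))


def hotspot_association(
    matrix: pd.DataFrame,
    kras_loh: Mapping[str, bool],
    panel: Sequence[str] = HOTSPOT_PANEL,
) -> pd.DataFrame:
    """Per-gene association between the gene's LOH and KRAS LOH.

    KRAS itself is excluded (its association with itself is vacuous); the
    remaining panel genes form the multiple-testing family for the BH
    adjustment. 2x2 tables use the continuity-corrected chi-square, falling
    back to Fisher's exact test when any expected count is below 5.
    """
    tested = [g for g in panel if g != "KRAS"]
    pvals, rows = [], []
    for gene in tested:
        loh_flags = {
            s: c.loh for s, c in matrix.loc[gene].items() if c is not None
        }
        samples = [s for s in loh_flags if s in kras_loh]
        try:
            table = build_contingency(
                ["loh" if loh_flags[s] else "no_loh" for s in samples],
                ["kras_loh" if kras_loh[s] else "no_kras_loh" for s in samples],
            )
        except ValueError:
            # gene constant across the cohort (or KRAS LOH single-level):
            # no association is testable
            rows.append({"p_value": float("nan")})
            continue
        if (table.expected() < 5).any():
            res = fisher_exact_2x2(table)
        else:
            res = chi_square(table, continuity_correction=True)
        pvals.append(res.p_value)
        rows.append({"p_value": res.p_value})
    adjusted = iter(bh_adjust(pvals))
    for row in rows:
        row["fdr_adjusted_p"] = (
            next(adjusted) if np.isfinite(row["p_value"]) else float("nan")
        )
    return pd.DataFrame(rows, index=pd.Index(tested, name="gene"))
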