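"""Synthetic cohort generation with planted, recorded ground truth.

Emulates the inputs of an early-stage lung-adenocarcinoma copy-number
study: per-tumor allele-specific segment profiles with a designated KRAS
locus where LOH is planted at a chosen prevalence, a regular SNP-probe
grid, gene annotation carrying the hotspot panel, log2 expression linearly
coupled to gene copy number, and exponential survival times with a
proportional-hazards effect of KRAS LOH.

Cohort-level defaults are anchored to the observed cohort the pipeline was
built around: 27% KRAS LOH (12/62 of those copy-neutral), 36.5% KRAS
mutation, group GII means 0.57 (LOH) vs 0.46 (no LOH), and an LOH overall-
survival hazard ratio of 0.65. The genome is scaled down (5 chromosomes x
60 Mb) so a full cohort generates in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalRecord,
    GeneAnnotation,
    ProbeMap,
    Segment,
    SegmentProfile,
    write_clinical,
    write_expression_matrix,
    write_gene_annotation,
    write_probe_map,
    write_segment_profiles,
)

__all__ = [
    "CohortSpec",
    "SyntheticGenome",
    "GroundTruth",
    "SyntheticCohort",
    "generate_genome",
    "generate_cohort",
    "generate_two_cohorts",
    "truth_report",
    "write_cohort",
]

_PANEL = (
    "KRAS", "EGFR", "TP53", "ALK", "ERBB2", "BRAF", "MET",
    "RET", "ROS1", "NTRK1", "NTRK2", "NTRK3", "STK11", "PIK3CA",
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_samples: int = 233
    kras_loh_prevalence: float = 0.27
    kras_mut_prevalence: float = 0.365
    egfr_mut_prevalence: float = 0.15
    copy_neutral_loh_fraction: float = 12 / 62
    gii_mean_loh: float = 0.57
    gii_mean_noloh: float = 0.46
    gii_sd: float = 0.08
    loh_hr: float = 0.65
    median_os_months: float = 60.0
    median_rfs_months: float = 80.0
    censoring_rate: float = 0.30
    cn_expr_slope: float = 0.5
    cn_expr_noise_sd: float = 0.9
    n_de_genes: int = 20
    de_shift: float = 1.5
    # genome model (scaled down from a full genome for fast end-to-end runs)
    n_chromosomes: int = 5
    chrom_size: int = 60_000_000
    probe_spacing: int = 15_000
    mean_segment_length: float = 3_000_000.0
    min_segment_length: int = 200_000
    n_background_genes: int = 600
    min_cellularity: float = 0.25

    def __post_init__(self) -> None:
        for name in ("kras_loh_prevalence", "kras_mut_prevalence",
                     "egfr_mut_prevalence", "copy_neutral_loh_fraction",
                     "gii_mean_loh", "gii_mean_noloh", "censoring_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.loh_hr > 0:
            raise ValueError("loh_hr must be positive")
        if self.gii_mean_loh < 0.02 and self.kras_loh_prevalence > 0:
            raise ValueError(
                "infeasible spec: a mandatory LOH segment at KRAS is incompatible "
                "with a near-zero LOH-group GII mean"
            )


@dataclass(frozen=True)
class SyntheticGenome:
    genes: tuple[GeneAnnotation, ...]
    probes: ProbeMap
    chrom_sizes: dict[str, int]
    kras: GeneAnnotation


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, per sample and per gene."""

    samples: pd.DataFrame        # index sample_id: kras_loh, copy_neutral_loh,
                                 # kras_mut, gii, os_hazard_multiplier
    de_genes: frozenset[str]
    cn_expr_slope: float


@dataclass(frozen=True)
class SyntheticCohort:
    genome: SyntheticGenome
    profiles: tuple[SegmentProfile, ...]
    expression: pd.DataFrame
    clinical: tuple[ClinicalRecord, ...]
    truth: GroundTruth


def generate_genome(spec: CohortSpec, seed: int) -> SyntheticGenome:
    """Chromosome sizes, a regular probe grid, and gene annotation.

    The hotspot panel genes are placed at fixed loci (KRAS on chr2, the
    stand-in for 12p); background genes are placed uniformly at random.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {
        f"chr{i + 1}": spec.chrom_size for i in range(spec.n_chromosomes)
    }
    chroms = list(chrom_sizes)
    probes = ProbeMap(
        {
            c: np.arange(spec.probe_spacing, size + 1, spec.probe_spacing)
            for c, size in chrom_sizes.items()
        }
    )
    genes: list[GeneAnnotation] = []
    kras_chrom = chroms[1 % len(chroms)]
    kras = GeneAnnotation("KRAS", kras_chrom, 25_000_000, 25_045_000)
    genes.append(kras)
    for i, symbol in enumerate(g for g in _PANEL if g != "KRAS"):
        chrom = chroms[i % len(chroms)]
        start = 5_000_000 + (i // len(chroms) + 1) * 8_000_000 + (i % len(chroms)) * 137
        genes.append(GeneAnnotation(symbol, chrom, start, start + 60_000))
    for i in range(spec.n_background_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(20_000, 120_000))
        start = int(rng.integers(1, chrom_sizes[chrom] - length))
        genes.append(GeneAnnotation(f"G{i:04d}", chrom, start, start + length))
    return SyntheticGenome(tuple(genes), probes, chrom_sizes, kras)


def _draw_ploidy(rng: np.random.Generator) -> float:
    # bimodal, mimicking near-diploid and genome-doubled tumors
    if rng.random() < 0.6:
        return float(np.clip(rng.normal(2.0, 0.12), 1.6, 2.4))
    return float(np.clip(rng.normal(3.5, 0.3), 2.6, 4.4))


def _neutral_alleles(total: int) -> tuple[int, int]:
    minor = max(1, total // 2) if total >= 2 else 0
    return total - minor, minor


def _draw_segments(
    spec: CohortSpec, rng: np.random.Generator, chrom: str, size: int,
    ploidy: float, gii_target: float,
) -> list[tuple[Segment, bool]]:
    """Random segmentation of one chromosome; returns (segment, aberrant)."""
    base = int(round(ploidy))
    segs = []
    pos = 1
    while pos <= size:
        length = max(
            spec.min_segment_length, int(rng.exponential(spec.mean_segment_length))
        )
        end = min(pos + length - 1, size)
        aberrant = rng.random() < gii_target
        if aberrant:
            k = int(rng.geometric(0.7))
            if rng.random() < 0.5:
                total = base + k
                minor = 0 if rng.random() < 0.2 else max(1, total // 2 - k)
            else:
                total = max(base - k, 1)
                minor = 0 if total == 1 or rng.random() < 0.7 else 1
        else:
            total = base
            _, minor = _neutral_alleles(total)
        segs.append((Segment(chrom, pos, end, total - minor, minor), aberrant))
        pos = end + 1
        # occasional unsegmented gap, as in real array profiles
        if rng.random() < 0.10 and pos <= size:
            pos += int(rng.integers(50_000, 500_000))
    return segs


def _plant_kras(
    segs: list[tuple[Segment, bool]],
    kras: GeneAnnotation,
    ploidy: float,
    loh: bool,
    copy_neutral: bool,
    rng: np.random.Generator,
) -> list[tuple[Segment, bool]]:
    """Replace whatever covers the KRAS span with one planted segment."""
    base = int(round(ploidy))
    if loh:
        if copy_neutral:
            planted = (base, 0)                    # one allele lost, total at ploidy
        else:
            planted = (max(base - 1, 1), 0)        # LOH through loss
    else:
        if rng.random() < 0.21:
            total = base + 1                       # background gain rate at the locus
            planted = _neutral_alleles(total)
        else:
            planted = _neutral_alleles(base)
    n_major, n_minor = planted
    # aberrant iff the ploidy-adjusted total rounds (half away from zero) to != 0
    aberrant = abs(n_major + n_minor - ploidy) >= 0.5
    out: list[tuple[Segment, bool]] = []
    placed = False
    for seg, ab in segs:
        if seg.end < kras.tx_start or seg.start > kras.tx_end:
            out.append((seg, ab))
            continue
        if seg.start < kras.tx_start:
            out.append((Segment(seg.chrom, seg.start, kras.tx_start - 1,
                                seg.n_major, seg.n_minor), ab))
        if not placed:
            out.append(
                (Segment(kras.chrom, kras.tx_start, kras.tx_end, n_major, n_minor),
                 aberrant)
            )
            placed = True
        if seg.end > kras.tx_end:
            out.append((Segment(seg.chrom, kras.tx_end + 1, seg.end,
                                seg.n_major, seg.n_minor), ab))
    if not placed:  # KRAS fell in an unsegmented gap
        out.append(
            (Segment(kras.chrom, kras.tx_start, kras.tx_end, n_major, n_minor), aberrant)
        )
        out.sort(key=lambda t: (t[0].chrom, t[0].start))
    return out


def _true_gii(
    segs: Sequence[tuple[Segment, bool]], probes: ProbeMap
) -> float:
    total = aberrant = 0
    for seg, ab in segs:
        n = probes.count_in(seg.chrom, seg.start, seg.end)
        total += n
        if ab:
            aberrant += n
    return aberrant / total if total else float("nan")


def _gene_total_cn(
    segs_by_chrom: Mapping[str, list[tuple[Segment, bool]]], gene: GeneAnnotation
) -> Optional[int]:
    mid = (gene.tx_start + gene.tx_end) // 2
    for seg, _ in segs_by_chrom.get(gene.chrom, ()):
        if seg.start <= mid <= seg.end:
            return seg.total_cn
    return None


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    genome: Optional[SyntheticGenome] = None,
    sample_prefix: str = "S",
    de_genes: Optional[Sequence[str]] = None,
) -> SyntheticCohort:
    """Generate one cohort: profiles, expression, clinical, ground truth.

    ``de_genes`` fixes the planted differentially expressed gene set, so two
    cohorts generated with different seeds can share it (cross-cohort
    intersection testing); by default the first ``n_de_genes`` background
    genes are used.
    """
    rng = np.random.default_rng(seed)
    if genome is None:
        genome = generate_genome(spec, seed)
    background = [g.gene_symbol for g in genome.genes if g.gene_symbol.startswith("G")]
    if de_genes is None:
        de_genes = background[: spec.n_de_genes]
    de_genes = frozenset(de_genes)

    profiles: list[SegmentProfile] = []
    truth_rows = []
    clinical: list[ClinicalRecord] = []
    gene_cn = {g.gene_symbol: [] for g in genome.genes}

    lam_os = math.log(2) / spec.median_os_months
    lam_rfs = math.log(2) / spec.median_rfs_months
    c = spec.censoring_rate
    lam_cens_os = lam_os * c / max(1 - c, 1e-9)
    lam_cens_rfs = lam_rfs * c / max(1 - c, 1e-9)

    for i in range(spec.n_samples):
        sid = f"{sample_prefix}{i:03d}"
        loh = bool(rng.random() < spec.kras_loh_prevalence)
        cn_loh = bool(loh and rng.random() < spec.copy_neutral_loh_fraction)
        kras_mut = bool(rng.random() < spec.kras_mut_prevalence)
        if kras_mut or spec.egfr_mut_prevalence == 0:
            egfr_mut = False  # mutually exclusive drivers
        else:
            egfr_mut = bool(
                rng.random()
                < spec.egfr_mut_prevalence / max(1 - spec.kras_mut_prevalence, 1e-9)
            )
        ploidy = _draw_ploidy(rng)
        gii_mean = spec.gii_mean_loh if loh else spec.gii_mean_noloh
        gii_target = float(np.clip(rng.normal(gii_mean, spec.gii_sd), 0.02, 0.98))

        segs: list[tuple[Segment, bool]] = []
        for chrom, size in genome.chrom_sizes.items():
            chrom_segs = _draw_segments(spec, rng, chrom, size, ploidy, gii_target)
            if chrom == genome.kras.chrom:
                chrom_segs = _plant_kras(
                    chrom_segs, genome.kras, ploidy, loh, cn_loh, rng
                )
            segs.extend(chrom_segs)
        by_chrom: dict[str, list[tuple[Segment, bool]]] = {}
        for seg, ab in segs:
            by_chrom.setdefault(seg.chrom, []).append((seg, ab))
        cellularity = float(np.clip(rng.normal(0.65, 0.15), spec.min_cellularity, 1.0))
        profiles.append(
            SegmentProfile(sid, ploidy, cellularity, tuple(s for s, _ in segs))
        )
        for g in genome.genes:
            gene_cn[g.gene_symbol].append(_gene_total_cn(by_chrom, g))

        haz_mult = spec.loh_hr if loh else 1.0
        t_os = rng.exponential(1 / (lam_os * haz_mult))
        c_os = min(rng.exponential(1 / lam_cens_os) if c > 0 else math.inf, 180.0)
        t_rfs = rng.exponential(1 / (lam_rfs * haz_mult))
        c_rfs = min(rng.exponential(1 / lam_cens_rfs) if c > 0 else math.inf, 180.0)
        clinical.append(
            ClinicalRecord(
                sample_id=sid,
                age=float(np.clip(rng.normal(64.5, 8.0), 39, 84)),
                sex="female" if rng.random() < 0.56 else "male",
                stage=str(rng.choice(["I", "II", "III"], p=[0.63, 0.22, 0.15])),
                ecog=int(rng.choice([0, 1, 2, 3], p=[0.55, 0.33, 0.08, 0.04]))
                if rng.random() > 0.05 else None,
                smoker=bool(rng.random() < 0.88),
                kras_mut=kras_mut,
                egfr_mut=egfr_mut,
                os_time=round(min(t_os, c_os), 2),
                os_event=int(t_os <= c_os),
                rfs_time=round(min(t_rfs, c_rfs), 2),
                rfs_event=int(t_rfs <= c_rfs),
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "kras_loh": loh,
                "copy_neutral_loh": cn_loh,
                "kras_mut": kras_mut,
                "gii": _true_gii(segs, genome.probes),
                "os_hazard_multiplier": haz_mult,
            }
        )

    sample_ids = [p.sample_id for p in profiles]
    truth_df = pd.DataFrame(truth_rows).set_index("sample_id")

    # expression: baseline + slope * (CN - 2) + noise; planted DE shift for
    # LOH samples on the designated gene set
    symbols = [g.gene_symbol for g in genome.genes]
    baseline = rng.normal(7.0, 1.5, size=len(symbols))
    expr = np.empty((len(symbols), len(sample_ids)))
    loh_flags = truth_df["kras_loh"].to_numpy()
    for gi, sym in enumerate(symbols):
        cn = np.array(
            [v if v is not None else 2 for v in gene_cn[sym]], dtype=float
        )
        noise = rng.normal(0.0, spec.cn_expr_noise_sd, size=len(sample_ids))
        expr[gi] = baseline[gi] + spec.cn_expr_slope * (cn - 2.0) + noise
        if sym in de_genes:
            expr[gi] = expr[gi] + spec.de_shift * loh_flags
    expression = pd.DataFrame(expr, index=pd.Index(symbols, name="gene"),
                              columns=sample_ids)

    return SyntheticCohort(
        genome=genome,
        profiles=tuple(profiles),
        expression=expression,
        clinical=tuple(clinical),
        truth=GroundTruth(truth_df, de_genes, spec.cn_expr_slope),
    )


def generate_two_cohorts(
    spec: CohortSpec, seed: int
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two cohorts on one genome sharing the planted DE gene set."""
    genome = generate_genome(spec, seed)
    a = generate_cohort(spec, seed + 1, genome=genome, sample_prefix="A")
    b = generate_cohort(spec, seed + 2, genome=genome, sample_prefix="B",
                        de_genes=a.truth.de_genes)
    return a, b


def truth_report(
    truth: GroundTruth,
    kras_loh_calls: Mapping[str, bool],
    gii: Optional[Mapping[str, float]] = None,
    hr_estimate: Optional[float] = None,
    de_genes: Optional[set] = None,
    all_genes: Optional[set] = None,
) -> dict[str, float]:
    """Recovery metrics of pipeline outputs against the planted truth."""
    planted = truth.samples
    if set(kras_loh_calls) != set(planted.index):
        raise ValueError("sample ids of calls do not match the ground truth")
    called = np.array([bool(kras_loh_calls[s]) for s in planted.index])
    metrics = {
        "loh_concordance": float((called == planted.kras_loh.to_numpy()).mean()),
        "recovered_loh_prevalence": float(called.mean()),
    }
    if gii is not None:
        est = np.array([gii[s] for s in planted.index])
        metrics["gii_mean_abs_error"] = float(np.abs(est - planted.gii).mean())
    if hr_estimate is not None:
        metrics["hr_estimate"] = float(hr_estimate)
        metrics["hr_planted"] = float(
            planted.os_hazard_multiplier[planted.kras_loh].iloc[0]
            if planted.kras_loh.any() else 1.0
        )
    if de_genes is not None:
        tp = len(de_genes & truth.de_genes)
        metrics["de_sensitivity"] = tp / len(truth.de_genes) if truth.de_genes else 1.0
        if all_genes is not None:
            negatives = all_genes - truth.de_genes
            fp = len(de_genes & negatives)
            metrics["de_specificity"] = (
                1 - fp / len(negatives) if negatives else 1.0
            )
    return metrics


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write every input format the readers understand, plus the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": out / "segments.tsv",
        "meta": out / "sample_meta.tsv",
        "annotation": out / "genes.refflat.txt",
        "probes": out / "probes.tsv",
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.tsv",
    }
    write_segment_profiles(cohort.profiles, paths["segments"], paths["meta"])
    write_gene_annotation(cohort.genome.genes, paths["annotation"])
    write_probe_map(cohort.genome.probes, paths["probes"])
    write_expression_matrix(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    cohort.truth.samples.to_csv(paths["truth"], sep="\t")
    return paths
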