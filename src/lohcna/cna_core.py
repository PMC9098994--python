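"""Ploidy-adjusted copy-number calling, LOH detection and genome instability.

The calling rules: the ploidy-adjusted total copy number of a segment is the
segment's total copy number minus the tumor's (real-valued) ploidy, rounded
to the nearest integer with ties going half away from zero. An adjusted copy
number >= +1 is a gain, <= -1 a loss, 0 neutral. LOH is the presence of a
single parental allele (minor allele copy number zero, at least one copy
remaining); copy-neutral LOH is LOH whose adjusted copy number is 0 — one
allele lost, the total unchanged relative to ploidy. The genome instability
index (GII) of a tumor is the fraction of array probes lying in gained or
lost segments, among probes lying in any segment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ProbeMap, Segment, SegmentProfile

__all__ = [
    "AberrationState",
    "SegmentCall",
    "GenomeInstabilityIndex",
    "ploidy_adjusted_cn",
    "classify_state",
    "segment_loh",
    "call_segment",
    "call_profile",
    "genome_instability_index",
    "dichotomize_gii",
]


class AberrationState(str, enum.Enum):
    GAIN = "gain"
    NEUTRAL = "neutral"
    LOSS = "loss"


@dataclass(frozen=True)
class SegmentCall:
    """Aberration call for one segment of one tumor."""

    segment: Segment
    adjusted_cn: int
    state: AberrationState
    loh: bool
    copy_neutral_loh: bool
    homozygous_deletion: bool


@dataclass(frozen=True)
class GenomeInstabilityIndex:
    value: float
    n_probes_aberrant: int
    n_probes_total: int


def ploidy_adjusted_cn(total_cn: int, ploidy: float) -> int:
    """Total copy number minus ploidy, rounded half away from zero."""
    if total_cn < 0:
        raise ValueError("total_cn must be nonnegative")
    if not ploidy > 0:
        raise ValueError("ploidy must be positive")
    diff = total_cn - ploidy
    return int(math.floor(diff + 0.5)) if diff >= 0 else -int(math.floor(-diff + 0.5))


def classify_state(adjusted_cn: int) -> AberrationState:
    if adjusted_cn >= 1:
        return AberrationState.GAIN
    if adjusted_cn <= -1:
        return AberrationState.LOSS
    return AberrationState.NEUTRAL


def segment_loh(n_major: int, n_minor: int) -> bool:
    """True iff a single parental allele remains.

    A homozygous deletion (0, 0) is not LOH — no allele is present — and is
    flagged separately by :func:`call_segment`.
    """
    if n_major < n_minor:
        raise ValueError(f"n_major={n_major} < n_minor={n_minor}")
    return n_minor == 0 and n_major >= 1


def call_segment(segment: Segment, ploidy: float) -> SegmentCall:
    adj = ploidy_adjusted_cn(segment.total_cn, ploidy)
    loh = segment_loh(segment.n_major, segment.n_minor)
    return SegmentCall(
        segment=segment,
        adjusted_cn=adj,
        state=classify_state(adj),
        loh=loh,
        copy_neutral_loh=loh and adj == 0,
        homozygous_deletion=segment.total_cn == 0,
    )


def call_profile(profile: SegmentProfile) -> list[SegmentCall]:
    """Call every segment of a tumor against its ploidy."""
    return [call_segment(seg, profile.ploidy) for seg in profile.segments]


def genome_instability_index(
    profile: SegmentProfile, probes: ProbeMap
) -> GenomeInstabilityIndex:
    """Fraction of in-segment probes lying in gained or lost segments.

    Probes outside every segment carry no call and enter neither the
    numerator nor the denominator.
    """
    n_total = 0
    n_aberrant = 0
    for call in call_profile(profile):
        seg = call.segment
        n = probes.count_in(seg.chrom, seg.start, seg.end)
        n_total += n
        if call.state is not AberrationState.NEUTRAL:
            n_aberrant += n
    if n_total == 0:
        raise ValueError(
            f"sample {profile.sample_id}: no probes fall within any segment; "
            "GII is undefined"
        )
    return GenomeInstabilityIndex(n_aberrant / n_total, n_aberrant, n_total)


def dichotomize_gii(
    values: Mapping[str, float], cutoff: float | None = None
) -> dict[str, str]:
    """Split per-sample GII into 'high'/'low' at a cutoff (default: cohort median).

    A value strictly above the cutoff is high; ties are low.
    """
    if len(values) < 2:
        raise ValueError("need at least two samples to dichotomize")
    if cutoff is None:
        cutoff = float(np.median(list(values.values())))
    return {k: ("high" if v > cutoff else "low") for k, v in values.items()}
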