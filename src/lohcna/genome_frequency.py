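"""Genome-wide gain/loss frequency tracks and per-interval group comparison.

The genome is tiled into fixed-width intervals (15 kb by default). Within an
interval a sample counts as gained or lost according to the state of the
segment containing the interval midpoint; samples with no segment there are
excluded from that interval's denominator. Group tracks are compared
interval-by-interval with the two-sample proportion test (continuity
corrected, equivalent to the Yates 2x2 chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cna_core import AberrationState, call_profile
from .io_formats import SegmentProfile

__all__ = [
    "GenomicInterval",
    "tile_genome",
    "aberration_frequency",
    "compare_group_frequencies",
    "export_frequency_plot_data",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def tile_genome(chrom_sizes: Mapping[str, int], width: int = 15_000) -> list[GenomicInterval]:
    """Tile each chromosome into consecutive width-bp intervals.

    The last interval is truncated at the chromosome end.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    intervals = []
    for chrom, size in chrom_sizes.items():
        for start in range(1, size + 1, width):
            intervals.append(GenomicInterval(chrom, start, min(start + width - 1, size)))
    return intervals


def _state_at(profile_calls, chrom: str, pos: int) -> Optional[AberrationState]:
    starts, ends, states = profile_calls.get(chrom, (None, None, None))
    if starts is None or starts.size == 0:
        return None
    i = int(np.searchsorted(starts, pos, "right")) - 1
    if i < 0 or pos > ends[i]:
        return None
    return states[i]


def _index_calls(profile: SegmentProfile):
    """Per-chromosome (starts, ends, states) arrays for midpoint lookup."""
    by_chrom: dict[str, list] = {}
    for call in call_profile(profile):
        seg = call.segment
        by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end, call.state))
    return {
        chrom: (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            [r[2] for r in rows],
        )
        for chrom, rows in by_chrom.items()
    }


def aberration_frequency(
    profiles: Sequence[SegmentProfile], intervals: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-interval gain/loss counts and frequencies over a sample group.

    Returns a DataFrame with columns chrom, start, end, n_gain, n_loss,
    n_total, gain_freq, loss_freq; frequencies are NaN where no sample has a
    segment at the interval midpoint.
    """
    indexed = [_index_calls(p) for p in profiles]
    rows = []
    for iv in intervals:
        n_gain = n_loss = n_total = 0
        for calls in indexed:
            state = _state_at(calls, iv.chrom, iv.midpoint)
            if state is None:
                continue
            n_total += 1
            if state is AberrationState.GAIN:
                n_gain += 1
            elif state is AberrationState.LOSS:
                n_loss += 1
        rows.append((iv.chrom, iv.start, iv.end, n_gain, n_loss, n_total))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_gain", "n_loss", "n_total"])
    with np.errstate(invalid="ignore"):
        df["gain_freq"] = np.where(df.n_total > 0, df.n_gain / df.n_total, np.nan)
        df["loss_freq"] = np.where(df.n_total > 0, df.n_loss / df.n_total, np.nan)
    return df


def _prop_test_p(x1: int, n1: int, x2: int, n2: int, correction: bool) -> float:
    """Two-sample proportion test p via the equivalent 2x2 chi-square."""
    if n1 == 0 or n2 == 0:
        return float("nan")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if (table.sum(axis=0) == 0).any():
        # both groups 0% or both 100%: proportions identical, no evidence
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(p)


def compare_group_frequencies(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    aberration: str,
    continuity_correction: bool = True,
) -> pd.Series:
    """Per-interval two-sided p-values for a gain (or loss) frequency difference."""
    if aberration not in ("gain", "loss"):
        raise ValueError("aberration must be 'gain' or 'loss'")
    key = ["chrom", "start", "end"]
    if not track_a[key].equals(track_b[key]):
        raise ValueError("tracks were built on different interval lists")
    col = f"n_{aberration}"
    p = [
        _prop_test_p(xa, na, xb, nb, continuity_correction)
        for xa, na, xb, nb in zip(track_a[col], track_a.n_total, track_b[col], track_b.n_total)
    ]
    return pd.Series(p, index=track_a.index, name=f"p_{aberration}")


def export_frequency_plot_data(tracks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Plot-ready table: gains on a positive scale, losses on a negative scale.

    One row per interval, ordered by chromosome then start, with
    ``gain_freq_<group>`` and ``neg_loss_freq_<group>`` columns per group.
    """
    groups = list(tracks)
    if not groups:
        raise ValueError("no tracks given")
    first = tracks[groups[0]]
    out = first[["chrom", "start", "end"]].copy()
    for name in groups:
        track = tracks[name]
        if not track[["chrom", "start", "end"]].equals(out[["chrom", "start", "end"]]):
            raise ValueError("tracks were built on different interval lists")
        out[f"gain_freq_{name}"] = track.gain_freq.values
        out[f"neg_loss_freq_{name}"] = -track.loss_freq.values
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_frequency_bed(track: pd.DataFrame, path) -> None:
    """Write a track as BED-like TSV (0-based half-open starts on disk)."""
    out = track.copy()
    out["start"] = out["start"] - 1
    out.to_csv(path, sep="\t", index=False)
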