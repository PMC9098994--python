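"""Readers, writers and domain types for all pipeline input formats.

All genomic coordinates are held internally as 1-based, inclusive on both
ends — the convention of SNP-array probe annotation. refFlat transcript
starts (0-based, half-open) are shifted on read. Strand is read but never
used: copy number is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "Segment",
    "SegmentProfile",
    "ProbeMap",
    "GeneAnnotation",
    "ClinicalRecord",
    "read_segment_profiles",
    "write_segment_profiles",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_probe_map",
    "write_probe_map",
    "filter_by_cellularity",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical",
    "write_clinical",
]

MISSING = "NA"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass(frozen=True)
class Segment:
    """A genomic region of constant allele-specific copy number.

    ``n_major`` and ``n_minor`` are the copy numbers of the more and less
    abundant parental allele; total copy number is their sum.
    """

    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start > end"
            )
        if self.n_minor < 0 or self.n_major < 0:
            raise ValidationError("allele copy numbers must be nonnegative")
        if self.n_major < self.n_minor:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has "
                f"n_major={self.n_major} < n_minor={self.n_minor}"
            )

    @property
    def total_cn(self) -> int:
        return self.n_major + self.n_minor

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SegmentProfile:
    """One tumor's allele-specific segmentation plus ASCAT ploidy/cellularity."""

    sample_id: str
    ploidy: float
    cellularity: float
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.ploidy > 0:
            raise ValidationError(f"sample {self.sample_id}: ploidy must be positive")
        if not 0 < self.cellularity <= 1:
            raise ValidationError(
                f"sample {self.sample_id}: cellularity must lie in (0, 1]"
            )
        object.__setattr__(self, "segments", _sort_segments(self.segments))
        by_chrom: dict[str, Segment] = {}
        for seg in self.segments:
            prev = by_chrom.get(seg.chrom)
            if prev is not None and seg.start <= prev.end:
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on {seg.chrom} "
                    f"({prev.start}-{prev.end} and {seg.start}-{seg.end})"
                )
            by_chrom[seg.chrom] = seg

    def segments_on(self, chrom: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.chrom == chrom)


def _sort_segments(segments: Iterable[Segment]) -> tuple[Segment, ...]:
    return tuple(sorted(segments, key=lambda s: (_chrom_key(s.chrom), s.start)))


def _chrom_key(chrom: str) -> tuple[int, str]:
    name = chrom.removeprefix("chr")
    return (0, f"{int(name):03d}") if name.isdigit() else (1, name)


class ProbeMap:
    """Sorted SNP-probe positions per chromosome (1-based)."""

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self._positions: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValidationError(
                    f"probe positions on {chrom} must be strictly increasing"
                )
            self._positions[chrom] = arr

    @property
    def chromosomes(self) -> list[str]:
        return list(self._positions)

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of probes within [start, end] inclusive."""
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left"))

    def n_probes(self) -> int:
        return sum(p.size for p in self._positions.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return self._positions.keys() == other._positions.keys() and all(
            np.array_equal(self._positions[c], other._positions[c])
            for c in self._positions
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's genomic span (union over transcripts), 1-based inclusive."""

    gene_symbol: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValidationError(f"{self.gene_symbol}: tx_start > tx_end")

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start + 1


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient covariates and OS/RFS endpoints (times in months from surgery)."""

    sample_id: str
    age: Optional[float] = None
    sex: Optional[str] = None          # "female" / "male"
    stage: Optional[str] = None        # "I" / "II" / "III"
    ecog: Optional[int] = None
    smoker: Optional[bool] = None
    kras_mut: Optional[bool] = None
    egfr_mut: Optional[bool] = None
    os_time: Optional[float] = None
    os_event: Optional[int] = None
    rfs_time: Optional[float] = None
    rfs_event: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("os_time", "rfs_time"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValidationError(f"sample {self.sample_id}: negative {name}")
        for name in ("os_event", "rfs_event"):
            val = getattr(self, name)
            if val is not None and val not in (0, 1):
                raise ValidationError(f"sample {self.sample_id}: {name} must be 0/1")


# ---------------------------------------------------------------------------
# segment profiles

_SEGMENT_COLS = ["sample", "chrom", "start", "end", "nMajor", "nMinor"]
_META_COLS = ["sample", "ploidy", "cellularity"]


def read_segment_profiles(path, meta_path) -> list[SegmentProfile]:
    """Read per-segment TSV plus the companion per-sample ploidy/cellularity TSV."""
    seg = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep="\t", float_precision="round_trip")
    for cols, df, name in ((_SEGMENT_COLS, seg, path), (_META_COLS, meta, meta_path)):
        missing = set(cols) - set(df.columns)
        if missing:
            raise FormatError(f"{name}: missing columns {sorted(missing)}")
    profiles = []
    grouped = {k: g for k, g in seg.groupby("sample", sort=False)}
    for row in meta.itertuples(index=False):
        g = grouped.pop(row.sample, None)
        segments = () if g is None else tuple(
            Segment(str(r.chrom), int(r.start), int(r.end), int(r.nMajor), int(r.nMinor))
            for r in g.itertuples(index=False)
        )
        profiles.append(
            SegmentProfile(str(row.sample), float(row.ploidy), float(row.cellularity), segments)
        )
    if grouped:
        raise FormatError(
            f"segment file has samples absent from metadata: {sorted(grouped)}"
        )
    return profiles


def write_segment_profiles(profiles: Sequence[SegmentProfile], path, meta_path) -> None:
    seg_rows = [
        (p.sample_id, s.chrom, s.start, s.end, s.n_major, s.n_minor)
        for p in profiles
        for s in p.segments
    ]
    pd.DataFrame(seg_rows, columns=_SEGMENT_COLS).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        [(p.sample_id, p.ploidy, p.cellularity) for p in profiles], columns=_META_COLS
    ).to_csv(meta_path, sep="\t", index=False)


def filter_by_cellularity(
    profiles: Sequence[SegmentProfile], min_fraction: float = 0.20
) -> list[SegmentProfile]:
    """Retain samples whose tumor cell fraction is strictly greater than the cutoff."""
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    return [p for p in profiles if p.cellularity > min_fraction]


# ---------------------------------------------------------------------------
# gene annotation (refFlat)

def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read refFlat; collapse duplicate symbols to the union transcript span.

    refFlat txStart is 0-based half-open; internally converted to 1-based
    inclusive. A symbol annotated on more than one chromosome is rejected.
    """
    spans: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 refFlat fields")
            symbol, _name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                tx_start = int(fields[4]) + 1
                tx_end = int(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            prev = spans.get(symbol)
            if prev is None:
                spans[symbol] = GeneAnnotation(symbol, chrom, tx_start, tx_end, strand)
            else:
                if prev.chrom != chrom:
                    raise ValidationError(
                        f"gene {symbol} annotated on multiple chromosomes "
                        f"({prev.chrom}, {chrom}); remove or rename one record"
                    )
                spans[symbol] = replace(
                    prev,
                    tx_start=min(prev.tx_start, tx_start),
                    tx_end=max(prev.tx_end, tx_end),
                )
    return list(spans.values())


def write_gene_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    """Write a minimal refFlat (one transcript per gene, 0-based starts)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [g.gene_symbol, g.gene_symbol, g.chrom, g.strand,
                     str(g.tx_start - 1), str(g.tx_end)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# probe map

def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "position"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns chrom, position")
    return ProbeMap(
        {str(c): g["position"].to_numpy() for c, g in df.groupby("chrom", sort=False)}
    )


def write_probe_map(probes: ProbeMap, path) -> None:
    frames = [
        pd.DataFrame({"chrom": chrom, "position": probes.positions(chrom)})
        for chrom in probes.chromosomes
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression

def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV.

    Rows sharing a gene symbol are averaged, the convention for genes
    measured by more than one array probe.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value") from exc
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    df.index.name = "gene"
    return df


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# clinical

_CLIN_COLS = [
    "sample", "age", "sex", "stage", "ecog", "smoker", "kras_mut", "egfr_mut",
    "os_time", "os_event", "rfs_time", "rfs_event",
]
_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False,
                "yes": True, "no": False}


def _opt(value, conv):
    if pd.isna(value) or str(value) == MISSING:
        return None
    return conv(value)


def _to_bool(value) -> bool:
    token = str(value).strip().lower()
    if token in _BOOL_TOKENS:
        return _BOOL_TOKENS[token]
    raise FormatError(f"cannot interpret {value!r} as boolean")


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_CLIN_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ClinicalRecord(
                sample_id=str(row.sample),
                age=_opt(row.age, float),
                sex=_opt(row.sex, str),
                stage=_opt(row.stage, str),
                ecog=_opt(row.ecog, lambda v: int(float(v))),
                smoker=_opt(row.smoker, _to_bool),
                kras_mut=_opt(row.kras_mut, _to_bool),
                egfr_mut=_opt(row.egfr_mut, _to_bool),
                os_time=_opt(row.os_time, float),
                os_event=_opt(row.os_event, lambda v: int(float(v))),
                rfs_time=_opt(row.rfs_time, float),
                rfs_event=_opt(row.rfs_event, lambda v: int(float(v))),
            )
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    rows = [
        [r.sample_id] + [
            _fmt(getattr(r, f))
            for f in ("age", "sex", "stage", "ecog", "smoker", "kras_mut",
                      "egfr_mut", "os_time", "os_event", "rfs_time", "rfs_event")
        ]
        for r in records
    ]
    pd.DataFrame(rows, columns=_CLIN_COLS).to_csv(path, sep="\t", index=False)
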