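"""Gene coordinates, CNV segment tables and their genomic intersection.

Coordinates are 0-based half-open (BED convention) throughout: a gene
``[100, 200)`` and a segment ``[200, 300)`` abut but do not overlap.  Any
overlap of at least one base pair counts; strand is ignored because copy
number is strand-agnostic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "CnvSegment",
    "read_genes",
    "read_segments",
    "intersect",
    "write_overlaps",
    "read_overlaps",
    "OVERLAP_COLUMNS",
]

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "total_cn", "avg_ploidy"]
OVERLAP_COLUMNS = [
    "symbol",
    "sample_id",
    "chrom",
    "seg_start",
    "seg_end",
    "total_cn",
    "avg_ploidy",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene locus: BED-style half-open interval plus a unique symbol."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.symbol}: invalid interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class CnvSegment:
    """One somatic copy-number segment call in one tumor sample.

    ``total_cn`` is the total (both-allele) DNA copy number of the segment;
    ``avg_ploidy`` is the sample's genome-wide average ploidy, which switches
    the loss/gain thresholds used downstream.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: float
    avg_ploidy: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"segment {self.sample_id} {self.chrom}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if not self.total_cn >= 0:
            raise ValueError(f"segment {self.sample_id}: total_cn must be >= 0")
        if not self.avg_ploidy > 0:
            raise ValueError(f"segment {self.sample_id}: avg_ploidy must be > 0")


def _normalize_chrom(chrom: str, strip_chr: bool) -> str:
    if strip_chr and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def read_genes(path: str | Path, strip_chr: bool = False) -> list[GeneRecord]:
    """Read a BED3+name file into validated gene records.

    Requires at least four columns (chrom, start, end, name).  Raises
    ``ValueError`` naming the offending line on malformed input or on a
    duplicated gene symbol.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, symbol = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if symbol in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate symbol {symbol!r}")
            seen.add(symbol)
            try:
                genes.append(
                    GeneRecord(symbol, _normalize_chrom(chrom, strip_chr), start, end)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def read_segments(path: str | Path, strip_chr: bool = False) -> list[CnvSegment]:
    """Read a CNV segment TSV (sample_id, chrom, start, end, total_cn, avg_ploidy)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    segments: list[CnvSegment] = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segments.append(
                CnvSegment(
                    sample_id=str(row.sample_id),
                    chrom=_normalize_chrom(str(row.chrom), strip_chr),
                    start=int(row.start),
                    end=int(row.end),
                    total_cn=float(row.total_cn),
                    avg_ploidy=float(row.avg_ploidy),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {row_idx}: {exc}") from exc
    return segments


def intersect(
    genes: Sequence[GeneRecord], segments: Sequence[CnvSegment]
) -> list[tuple[GeneRecord, CnvSegment]]:
    """All (gene, segment) pairs sharing >= 1 bp on the same chromosome.

    Sort-then-sweep per chromosome: both inputs are sorted by start; a heap
    of "active" genes keyed by end coordinate is maintained while sweeping
    segments in start order, so runtime is O((n+m) log n + k) for k reported
    pairs rather than the quadratic all-pairs scan.  Output is sorted by
    (gene symbol, sample id, segment start) and is invariant to the input
    ordering of either list.
    """
    by_chrom_genes: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)
    by_chrom_segs: dict[str, list[CnvSegment]] = {}
    for s in segments:
        by_chrom_segs.setdefault(s.chrom, []).append(s)

    pairs: list[tuple[GeneRecord, CnvSegment]] = []
    for chrom, segs in by_chrom_segs.items():
        chrom_genes = by_chrom_genes.get(chrom)
        if not chrom_genes:
            continue
        chrom_genes = sorted(chrom_genes, key=lambda g: (g.start, g.end, g.symbol))
        segs = sorted(segs, key=lambda s: (s.start, s.end, s.sample_id))
        active: list[tuple[int, int]] = []  # (gene end, index into chrom_genes)
        gi = 0
        for seg in segs:
            while gi < len(chrom_genes) and chrom_genes[gi].start < seg.end:
                heapq.heappush(active, (chrom_genes[gi].end, gi))
                gi += 1
            while active and active[0][0] <= seg.start:
                heapq.heappop(active)
            # remaining active genes all have end > seg.start; the start
            # condition must be rechecked because a gene activated by an
            # earlier, longer segment may start beyond this segment's end
            for _, idx in active:
                if chrom_genes[idx].start < seg.end:
                    pairs.append((chrom_genes[idx], seg))
    pairs.sort(key=lambda p: (p[0].symbol, p[1].sample_id, p[1].start, p[1].end))
    return pairs


def overlaps_frame(pairs: Iterable[tuple[GeneRecord, CnvSegment]]) -> pd.DataFrame:
    """Tabulate intersection pairs as a DataFrame with OVERLAP_COLUMNS."""
    rows = [
        (g.symbol, s.sample_id, s.chrom, s.start, s.end, s.total_cn, s.avg_ploidy)
        for g, s in pairs
    ]
    return pd.DataFrame(rows, columns=OVERLAP_COLUMNS)


def write_overlaps(
    pairs: Iterable[tuple[GeneRecord, CnvSegment]], path: str | Path
) -> pd.DataFrame:
    df = overlaps_frame(pairs)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_overlaps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "sample_id": str, "chrom": str})
    missing = [c for c in OVERLAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
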