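"""Core domain types and interval algebra.

Every genomic coordinate in this package is 0-based, half-open
(BED-native).  Sources that use 1-based inclusive coordinates (GTF,
dbSNP-style variant positions) are converted on read, so a single
overlap algebra serves every module.
"""
from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "Loop",
    "GeneModel",
    "PeakSet",
    "VariantRecord",
    "IntervalIndex",
    "sort_intervals",
    "merge_intervals",
    "interval_gap",
    "overlap_length",
]

KNOWN_MARKS = frozenset(
    {
        "H3K27ac",
        "H3K27me3",
        "H3K4me1",
        "H3K4me2",
        "H3K4me3",
        "H3K36me3",
        "H3K9me3",
        "CTCF",
        "ATAC",
    }
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chrom/start/end span, 0-based half-open; the atom of overlap algebra."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def with_score(self, score: float) -> "GenomicInterval":
        return replace(self, score=score)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases; 0 when on different chromosomes or disjoint."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Edge-to-edge gap in bp; 0 if the intervals overlap or abut.

    Returns None for intervals on different chromosomes (distance
    undefined).
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union-merge intervals whose edge-to-edge gap is <= ``gap``.

    ``gap=0`` merges overlapping and book-ended intervals.  The merged
    interval keeps no name/score (constituents are heterogeneous).
    """
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class IntervalIndex:
    """Per-chromosome overlap queries over a fixed interval set.

    Built once from any iterable of intervals; query cost is
    O(log n + hits) using a sorted-start list plus a running maximum of
    ends (sufficient at this package's scales and dependency-free).
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self._starts[chrom] = [iv.start for iv in ivs]
            running = []
            m = -1
            for iv in ivs:
                m = max(m, iv.end)
                running.append(m)
            self._maxend[chrom] = running

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All stored intervals sharing >=1 bp with ``query``."""
        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return []
        starts = self._starts[query.chrom]
        hi = bisect_left(starts, query.end)  # candidates start before query.end
        hits = []
        # scan backwards until the running max-end falls below query.start
        for i in range(hi - 1, -1, -1):
            if self._maxend[query.chrom][i] <= query.start:
                break
            iv = ivs[i]
            if iv.end > query.start:
                hits.append(iv)
        hits.reverse()
        return hits

    def any_overlap(self, query: GenomicInterval) -> bool:
        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return False
        starts = self._starts[query.chrom]
        hi = bisect_left(starts, query.end)
        return hi > 0 and self._maxend[query.chrom][hi - 1] > query.start

    def at_pos(self, chrom: str, pos: int) -> list[GenomicInterval]:
        return self.overlapping(GenomicInterval(chrom, pos, pos + 1))


def warn_unshared_chroms(
    left: Iterable[str], right: Iterable[str], context: str
) -> None:
    """Chromosome naming is exact-match only; surface mismatches loudly."""
    ls, rs = set(left), set(right)
    diff = ls.symmetric_difference(rs)
    if diff and ls and rs:
        warnings.warn(
            f"{context}: chromosome names not shared between inputs: "
            f"{sorted(diff)} (no aliasing is applied)",
            stacklevel=3,
        )


@dataclass(frozen=True)
class Loop:
    """An ordered pair of anchor intervals with per-sample presence flags.

    Anchors are normalized so (chrom1, start1) <= (chrom2, start2)
    lexicographically; ``canonical`` enforces this.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: Optional[float] = None
    samples: frozenset[str] = frozenset()

    @staticmethod
    def canonical(
        anchor1: GenomicInterval,
        anchor2: GenomicInterval,
        score: Optional[float] = None,
        samples: Iterable[str] = (),
    ) -> "Loop":
        k1 = (anchor1.chrom, anchor1.start, anchor1.end)
        k2 = (anchor2.chrom, anchor2.start, anchor2.end)
        if k2 < k1:
            anchor1, anchor2 = anchor2, anchor1
        return Loop(anchor1, anchor2, score=score, samples=frozenset(samples))

    @property
    def key(self) -> tuple:
        return (
            self.anchor1.chrom,
            self.anchor1.start,
            self.anchor1.end,
            self.anchor2.chrom,
            self.anchor2.start,
            self.anchor2.end,
        )

    def is_intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS and derived promoter window.

    On the + strand the TSS is body.start; on the − strand it is
    body.end − 1.  The promoter covers ``up`` bases 5′ of transcription
    and ``down`` bases 3′, always containing the TSS; see
    :func:`promoter_interval`.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    body: GenomicInterval
    promoter: GenomicInterval

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1


def promoter_interval(
    chrom: str, strand: str, tss: int, up: int, down: int
) -> GenomicInterval:
    """Strand-aware promoter window around a TSS, clipped at 0.

    + strand: [tss − up, tss + down); − strand mirrored so that the
    window still contains the TSS: [tss − down + 1, tss + up + 1).
    """
    if strand == "+":
        start, end = tss - up, tss + down
    elif strand == "-":
        start, end = tss - down + 1, tss + up + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    start = max(0, start)
    if start >= end:
        raise ValueError(
            f"empty promoter window (up={up}, down={down}) at {chrom}:{tss}"
        )
    return GenomicInterval(chrom, start, end)


@dataclass
class PeakSet:
    """Called peaks for one mark / condition / replicate."""

    mark: str
    condition: str
    replicate: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.mark not in KNOWN_MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; known: {sorted(KNOWN_MARKS)}")
        self.intervals = sort_intervals(self.intervals)


@dataclass(frozen=True)
class VariantRecord:
    """A GWAS lead variant or LD proxy at a single base (0-based pos)."""

    rsid: str
    chrom: str
    pos: int
    trait: str
    is_lead: bool
    lead_rsid: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {self.r2}")
        if self.pos < 0:
            raise ValueError("variant position must be non-negative")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, name=self.rsid)
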