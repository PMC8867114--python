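"""Core genomic data model and interval arithmetic.

Every coordinate inside the pipeline is 0-based half-open (BED convention);
1-based formats (GTF) are converted at the I/O boundary.  Overlap means at
least one shared base, so under half-open arithmetic ``a.start < b.end and
b.start < a.end``; adjacent intervals do not overlap.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base (strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge intervals connected by chains of >=1 bp overlaps.

    Adjacent-but-not-overlapping intervals ([0,10) and [10,20)) are kept
    separate.  The result is sorted by (chrom, start) and pairwise
    non-overlapping; strand is dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict: adjacency does not merge
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


class IntervalIndex:
    """Membership queries against a fixed interval set.

    Intervals are merged per chromosome at construction, after which a
    query resolves with two bisections.  Suits the pipeline's repeated
    "does this peak touch any blacklist/other-replicate region?" pattern.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        ends = self._ends[chrom]
        # first merged interval with end > start
        i = bisect.bisect_right(ends, start)
        return i < len(starts) and starts[i] < end

    def which(self, chrom: str, start: int, end: int) -> Optional[int]:
        """Index (within this chromosome) of the first merged interval hit."""
        starts = self._starts.get(chrom)
        if starts is None:
            return None
        i = bisect.bisect_right(self._ends[chrom], start)
        if i < len(starts) and starts[i] < end:
            return i
        return None

    def chrom_intervals(self, chrom: str) -> list[GenomicInterval]:
        return [
            GenomicInterval(chrom, s, e)
            for s, e in zip(self._starts.get(chrom, []), self._ends.get(chrom, []))
        ]


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus the caller's point and p estimates.

    ``summit_offset`` is the offset of the summit from ``interval.start``
    (``None`` when the caller reported no summit); ``neglog10_p`` is
    -log10 of the peak p-value.
    """

    interval: GenomicInterval
    summit_offset: Optional[int] = None
    neglog10_p: float = 0.0
    source_id: str = ""
    name: str = "."
    score: int = 0
    signal_value: float = 0.0
    neglog10_q: float = -1.0

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.neglog10_p < 0:
            raise ValueError("neglog10_p must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit_pos(self) -> Optional[int]:
        """Absolute genomic position of the summit, if reported."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset


@dataclass
class PeakSet:
    """A named collection of peaks kept sorted by (chrom, start, end)."""

    name: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.chrom, p.start, p.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def subset(self, keep: Sequence[bool], name: Optional[str] = None) -> "PeakSet":
        if len(keep) != len(self.peaks):
            raise ValueError("mask length mismatch")
        return PeakSet(
            name if name is not None else self.name,
            [p for p, k in zip(self.peaks, keep) if k],
        )


@dataclass(frozen=True)
class TagAlignment:
    """A single-end sequencing tag reduced to its mapped 5' base and strand.

    For a minus-strand BED record ``[start, end)`` the 5' end is ``end - 1``
    (the highest coordinate of the read), which is what 3'-ward extension
    must anchor on.
    """

    chrom: str
    five_prime_pos: int
    strand: str
    read_length: int = 50

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("tag strand must be '+' or '-'")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.five_prime_pos < 0:
            raise ValueError("five_prime_pos must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed over its transcripts.

    ``tss`` is the 0-based position of the 5'-most transcribed base in gene
    orientation (the highest genomic coordinate for minus-strand genes) and
    ``tes`` the 3'-most; ``union_exon_length`` is the number of bases
    covered by the union of all exons.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"
    union_exon_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise ValueError(f"gene {self.gene_id}: - strand requires tes < tss")
        if self.union_exon_length <= 0:
            raise ValueError(f"gene {self.gene_id}: union_exon_length must be > 0")

    @property
    def span(self) -> GenomicInterval:
        lo = min(self.tss, self.tes)
        hi = max(self.tss, self.tes) + 1
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    def to_genomic(self, offset: int, anchor: int) -> int:
        """Map a stranded offset from ``anchor`` to a genomic position."""
        return anchor + offset if self.strand == "+" else anchor - offset

    def stranded_offset(self, pos: int, anchor: int) -> int:
        """Signed offset of genomic ``pos`` from ``anchor``, 5'->3' positive."""
        return pos - anchor if self.strand == "+" else anchor - pos


def union_exon_length(exons: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of the exon intervals."""
    return sum(len(iv) for iv in merge_intervals(exons))


def stranded_window(
    gene: GeneModel, anchor: int, window: tuple[int, int]
) -> Optional[GenomicInterval]:
    """Genomic interval of a half-open stranded window around ``anchor``.

    ``window=(lo, hi)`` covers stranded offsets ``lo..hi-1``; for a minus
    strand gene the genomic interval mirrors around the anchor.  The result
    is clipped at position 0; ``None`` when the window falls entirely
    before the chromosome start.
    """
    lo, hi = window
    if gene.strand == "+":
        start, end = anchor + lo, anchor + hi
    else:
        start, end = anchor - hi + 1, anchor - lo + 1
    start = max(start, 0)
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end)
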