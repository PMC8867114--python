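"""Peak-to-gene annotation.

Each peak is reduced to a single anchor base (the summit when the caller
reported one, else the interval midpoint), assigned to the gene whose TSS
is closest, and classified into one of seven location categories defined by
fixed windows in stranded gene coordinates:

* upstream      [TSS-5000, TSS-1000)
* promoter      [TSS-1000, TSS+500)
* exon / intron anchor inside the gene body, in / not in an exon
* TES           [TES-500, TES+1000)
* downstream    [TES+1000, TES+5000)
* intergenic    anything else

Windows of short genes can overlap; a fixed precedence (promoter > TES >
upstream > downstream > exon > intron) makes the seven categories a
partition, so every peak lands in exactly one.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .config import PipelineConfig
from .intervals import GeneModel, GenomicInterval, Peak, PeakSet

log = logging.getLogger(__name__)

CATEGORIES = (
    "upstream",
    "promoter",
    "exon",
    "intron",
    "TES",
    "downstream",
    "intergenic",
)


@dataclass(frozen=True)
class AnnotationResult:
    peak: Peak
    gene_id: Optional[str]
    signed_distance: Optional[int]  # anchor - TSS in gene orientation
    category: str


def anchor_point(peak: Peak) -> int:
    """Genomic position annotation measures from: summit, else midpoint."""
    if peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end) // 2


class TssIndex:
    """Nearest-TSS lookup over a fixed gene list.

    Ties in genomic distance are broken by smaller absolute stranded
    distance, then lexicographically smaller gene_id, so annotation is
    deterministic regardless of input order.
    """

    def __init__(self, genes: list[GeneModel]) -> None:
        self._by_chrom: dict[str, list[tuple[int, str, GeneModel]]] = defaultdict(list)
        for g in genes:
            self._by_chrom[g.chrom].append((g.tss, g.gene_id, g))
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda t: (t[0], t[1]))

    def nearest(self, chrom: str, pos: int) -> Optional[tuple[GeneModel, int]]:
        """(gene, signed stranded distance) of the closest TSS, or None."""
        entries = self._by_chrom.get(chrom)
        if not entries:
            return None
        tss_list = [t[0] for t in entries]
        i = bisect.bisect_left(tss_list, pos)
        neighbors = [tss_list[j] for j in (i - 1, i) if 0 <= j < len(entries)]
        dist = min(abs(pos - t) for t in neighbors)
        candidates: list[tuple[int, str, GeneModel]] = []
        for tss in {pos - dist, pos + dist}:
            lo = bisect.bisect_left(tss_list, tss)
            hi = bisect.bisect_right(tss_list, tss)
            candidates.extend(entries[lo:hi])
        best = min(candidates, key=lambda t: t[1])  # equal distance: gene_id
        gene = best[2]
        return gene, gene.stranded_offset(pos, gene.tss)


def nearest_tss_gene(
    peak: Peak, genes: list[GeneModel]
) -> Optional[tuple[str, int]]:
    """Convenience single-peak wrapper around :class:`TssIndex`."""
    hit = TssIndex(genes).nearest(peak.chrom, anchor_point(peak))
    if hit is None:
        return None
    gene, dist = hit
    return gene.gene_id, dist


def classify_anchor(
    anchor: int, gene: GeneModel, cfg: PipelineConfig
) -> str:
    """Category of an anchor position relative to its assigned gene."""
    d_tss = gene.stranded_offset(anchor, gene.tss)
    d_tes = gene.stranded_offset(anchor, gene.tes)

    def _in(offset: int, window: tuple[int, int]) -> bool:
        return window[0] <= offset < window[1]

    if _in(d_tss, cfg.promoter_window):
        return "promoter"
    if _in(d_tes, cfg.tes_window):
        return "TES"
    if _in(d_tss, cfg.upstream_window):
        return "upstream"
    if _in(d_tes, cfg.downstream_window):
        return "downstream"
    span = gene.span
    if span.start <= anchor < span.end:
        for exon in gene.exons:
            if exon.start <= anchor < exon.end:
                return "exon"
        return "intron"
    return "intergenic"


def classify_peak(peak: Peak, gene: GeneModel, cfg: PipelineConfig) -> str:
    return classify_anchor(anchor_point(peak), gene, cfg)


def annotate_peaks(
    peaks: PeakSet, genes: list[GeneModel], cfg: PipelineConfig
) -> list[AnnotationResult]:
    """One :class:`AnnotationResult` per peak (nearest TSS + category).

    Peaks on chromosomes with no gene are reported intergenic with no
    assigned gene (counted in the log), not an error.
    """
    index = TssIndex(genes)
    results: list[AnnotationResult] = []
    n_orphan = 0
    for p in peaks:
        anchor = anchor_point(p)
        hit = index.nearest(p.chrom, anchor)
        if hit is None:
            n_orphan += 1
            results.append(AnnotationResult(p, None, None, "intergenic"))
            continue
        gene, dist = hit
        results.append(
            AnnotationResult(p, gene.gene_id, dist, classify_anchor(anchor, gene, cfg))
        )
    if n_orphan:
        log.info("%d peaks on chromosomes without genes -> intergenic", n_orphan)
    return results


def genomic_distribution(
    peaks: PeakSet, genes: list[GeneModel], cfg: PipelineConfig
) -> tuple[pd.DataFrame, list[AnnotationResult]]:
    """Category counts and fractions over a peak set (pie-chart table).

    Returns the 7-row distribution table (category, count, fraction) and
    the full per-peak annotation.  Fractions sum to one; empty input is an
    error because fractions would be undefined.
    """
    if len(peaks) == 0:
        raise ValueError(
            "genomic_distribution needs a non-empty peak set "
            "(fractions are undefined for 0 peaks)"
        )
    results = annotate_peaks(peaks, genes, cfg)
    counts = Counter(r.category for r in results)
    n = len(results)
    table = pd.DataFrame(
        {
            "category": CATEGORIES,
            "count": [counts.get(c, 0) for c in CATEGORIES],
        }
    )
    table["fraction"] = table["count"] / n
    return table, results


def annotation_table(results: list[AnnotationResult]) -> pd.DataFrame:
    """Long-format per-peak annotation (TSV-ready)."""
    return pd.DataFrame(
        {
            "chrom": [r.peak.chrom for r in results],
            "start": [r.peak.start for r in results],
            "end": [r.peak.end for r in results],
            "name": [r.peak.name for r in results],
            "anchor": [anchor_point(r.peak) for r in results],
            "gene_id": [r.gene_id or "" for r in results],
            "signed_distance": [
                r.signed_distance if r.signed_distance is not None else ""
                for r in results
            ],
            "category": [r.category for r in results],
        }
    )


def extract_summit_windows(
    peaks: PeakSet,
    genome,
    cfg: PipelineConfig,
) -> list[tuple[str, str]]:
    """Summit-centered sequences for motif discovery input.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of chromosome name to
    sliceable sequence).  Each peak yields the uppercase sequence of
    ``[anchor - summit_flank, anchor + summit_flank)``; peaks whose window
    crosses a chromosome boundary are dropped and counted in the log.
    Record ids are ``chrom:start-end``.
    """
    flank = cfg.summit_flank
    records: list[tuple[str, str]] = []
    n_dropped = 0
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"chromosome {p.chrom!r} absent from genome FASTA")
        chrom_len = len(genome[p.chrom])
        anchor = anchor_point(p)
        lo, hi = anchor - flank, anchor + flank
        if lo < 0 or hi > chrom_len:
            n_dropped += 1
            continue
        seq = str(genome[p.chrom][lo:hi]).upper()
        records.append((f"{p.chrom}:{lo}-{hi}", seq))
    if n_dropped:
        log.info("%d summit windows crossed a chromosome boundary; dropped", n_dropped)
    return records
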