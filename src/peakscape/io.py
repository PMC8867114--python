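"""Readers and writers for the standard formats the pipeline touches.

BED-family formats (BED3/6, tagAlign, ENCODE narrowPeak, bedGraph) are
0-based half-open on disk and are passed through unchanged; GTF is 1-based
inclusive and is converted to the internal half-open convention on read.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gffutils

from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    TagAlignment,
    merge_intervals,
    union_exon_length,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_HEADER_PREFIXES = ("browser", "track", "#")


class FormatError(ValueError):
    """Malformed record in an input file (message names the line)."""


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(_HEADER_PREFIXES):
                continue
            yield lineno, line


def _parse_span(fields: Sequence[str], path: PathLike, lineno: int) -> tuple[str, int, int]:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}, line {lineno}: malformed BED record ({exc})")
    if start < 0 or start >= end:
        raise FormatError(
            f"{path}, line {lineno}: invalid coordinates start={start} end={end}"
        )
    return chrom, start, end


def read_bed(
    path: PathLike,
) -> Union[list[GenomicInterval], list[TagAlignment]]:
    """Read a BED file; 6-column records become :class:`TagAlignment`.

    3–5 column records yield plain intervals sorted by (chrom, start).
    6-column records are interpreted as single-end tags: the 5' position is
    ``start`` on the plus strand and ``end - 1`` on the minus strand, and
    ``read_length = end - start``.  Tag order is preserved as on disk.
    """
    intervals: list[GenomicInterval] = []
    tags: list[TagAlignment] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        chrom, start, end = _parse_span(fields, path, lineno)
        if len(fields) >= 6 and fields[5] in ("+", "-"):
            five = start if fields[5] == "+" else end - 1
            tags.append(TagAlignment(chrom, five, fields[5], end - start))
        else:
            intervals.append(GenomicInterval(chrom, start, end))
    if tags and intervals:
        raise FormatError(f"{path}: mixed stranded and unstranded BED records")
    if tags:
        return tags
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def read_narrowpeak(path: PathLike, source_id: str = "") -> PeakSet:
    """Read a 10-column ENCODE narrowPeak file into a sorted :class:`PeakSet`.

    Column 8 is -log10(pValue), column 10 the summit offset from start
    (-1 meaning no summit reported).
    """
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 10:
            raise FormatError(
                f"{path}, line {lineno}: narrowPeak needs 10 columns, "
                f"got {len(fields)}"
            )
        chrom, start, end = _parse_span(fields, path, lineno)
        try:
            score = int(fields[4])
            signal = float(fields[6])
            neglog10_p = float(fields[7])
            neglog10_q = float(fields[8])
            summit = int(fields[9])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}")
        if neglog10_p < 0:
            raise FormatError(
                f"{path}, line {lineno}: negative -log10 p-value {neglog10_p}"
            )
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end, fields[5] if fields[5] in "+-" else "."),
                summit_offset=None if summit == -1 else summit,
                neglog10_p=neglog10_p,
                source_id=source_id,
                name=fields[3],
                score=score,
                signal_value=signal,
                neglog10_q=neglog10_q,
            )
        )
    return PeakSet(source_id or str(path), peaks)


def write_narrowpeak(peaks: PeakSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    (
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.interval.strand if p.interval.strand != "." else ".",
                        _fmt(p.signal_value),
                        _fmt(p.neglog10_p),
                        _fmt(p.neglog10_q),
                        str(-1 if p.summit_offset is None else p.summit_offset),
                    )
                )
                + "\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_tagalign(tags: Iterable[TagAlignment], path: PathLike) -> None:
    """Write tags as 6-column BED (tagAlign dialect, sequence column '.')."""
    with open(path, "w") as fh:
        for t in tags:
            if t.strand == "+":
                start = t.five_prime_pos
            else:
                start = t.five_prime_pos - t.read_length + 1
            end = start + t.read_length
            fh.write(f"{t.chrom}\t{start}\t{end}\t.\t0\t{t.strand}\n")


def _fmt(x: float) -> str:
    """Compact fixed-ish float formatting stable across platforms."""
    s = f"{x:.6g}"
    return s


def read_gtf_genes(path: PathLike) -> list[GeneModel]:
    """Load gene-level models from a GENCODE-dialect GTF.

    All transcripts of a gene are collapsed: the TSS is the 5'-most
    transcribed base over all transcripts, the TES the 3'-most, and the
    exon set is the union of all transcript exons.  GTF's 1-based
    inclusive coordinates are converted to 0-based half-open here.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        if g.strand not in ("+", "-"):
            raise FormatError(f"gene {gene_id}: strand {g.strand!r} not oriented")
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, g.strand)
            for e in db.children(g, featuretype="exon")
        ]
        if not exons:
            raise FormatError(f"gene {gene_id}: no exon features in GTF")
        lo = min(e.start for e in exons)
        hi = max(e.end for e in exons)
        tss, tes = (lo, hi - 1) if g.strand == "+" else (hi - 1, lo)
        biotype = (
            g.attributes.get("gene_type") or g.attributes.get("gene_biotype") or ["unknown"]
        )[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=g.seqid,
                strand=g.strand,
                tss=tss,
                tes=tes,
                exons=tuple(merge_intervals(exons)),
                biotype=biotype,
                union_exon_length=union_exon_length(exons),
            )
        )
    genes.sort(key=lambda g: (g.chrom, min(g.tss, g.tes), g.gene_id))
    return genes


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def validate_chrom_namespaces(
    a: Iterable[str], b: Iterable[str], what_a: str = "peaks", what_b: str = "genes"
) -> bool:
    """Warn when two inputs share no chromosome names.

    A disjoint namespace (e.g. ``chr1`` vs ``1``) silently annotates
    nothing; chromosome matching is exact string equality everywhere, so
    surface the mismatch loudly.  Returns True when the namespaces overlap.
    """
    sa, sb = set(a), set(b)
    if sa and sb and not (sa & sb):
        warnings.warn(
            f"chromosome names of {what_a} ({sorted(sa)[:3]}...) and {what_b} "
            f"({sorted(sb)[:3]}...) are disjoint; annotation will be empty",
            stacklevel=2,
        )
        return False
    return True
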