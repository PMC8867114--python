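"""Normalized coverage tracks and TSS metaprofiles from tag alignments.

The chain mirrors a standard single-end ChIP-seq quantification: tags are
deduplicated on their mapped 5' position (one copy kept per (chrom, 5'
position, strand)), replaced by fixed-size fragments extending 3'-ward
from the 5' end, piled up per base, scaled to a common library size
(default 10 M tags) and averaged within fixed-width bins (default 10 bp).
Metaprofiles average the same normalized per-base signal over windows
centered on many TSSs, optionally flipping minus-strand windows so the bin
axis always runs 5'->3'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .config import PipelineConfig
from .intervals import GeneModel, GenomicInterval, TagAlignment

log = logging.getLogger(__name__)


@dataclass
class SignalTrack:
    """Binned, depth-normalized coverage.

    ``values[chrom][j]`` is the mean normalized per-base depth over the
    half-open bin ``[j*bin_size, (j+1)*bin_size)``; positions past the
    chromosome end count as zero depth so every bin averages over
    ``bin_size`` bases.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    n_tags_used: int
    scale_factor: float

    def total_mass(self) -> float:
        """Sum over bins of value * bin_size (== scaled fragment bases)."""
        return float(
            sum(v.sum() for v in self.values.values()) * self.bin_size
        )


@dataclass
class Metaprofile:
    """Average normalized depth in fixed bins around many TSSs."""

    bin_size: int
    flank: int
    values: np.ndarray  # length 2*flank/bin_size
    n_tss: int
    n_tags_used: int

    @property
    def bin_center_offsets(self) -> np.ndarray:
        """Stranded offset of each bin center from the TSS."""
        starts = np.arange(-self.flank, self.flank, self.bin_size)
        return starts + (self.bin_size - 1) / 2.0


def dedup_tags(tags: Iterable[TagAlignment]) -> list[TagAlignment]:
    """Collapse PCR duplicates: one tag per (chrom, 5' position, strand).

    The first occurrence wins.  Tags on opposite strands at the same
    position are distinct events and are both retained.
    """
    seen: set[tuple[str, int, str]] = set()
    out: list[TagAlignment] = []
    for t in tags:
        key = (t.chrom, t.five_prime_pos, t.strand)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def extend_tags(
    tags: Iterable[TagAlignment],
    cfg: PipelineConfig,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[GenomicInterval]:
    """Replace each tag by its 3'-ward extended fragment.

    In the default ``extension_mode='extsize'`` a tag becomes an
    ``extsize`` bp fragment anchored at its 5' end (plus strand
    ``[p, p+E)``, minus strand ``[p-E+1, p+1)``); ``'append'`` instead
    keeps the read and adds ``extsize`` bases beyond its 3' terminus.
    With ``chrom_lengths`` fragments are clipped to ``[0, length)``; an
    unknown chromosome is then an error.
    """
    ext = cfg.extsize
    out: list[GenomicInterval] = []
    for t in tags:
        length = ext if cfg.extension_mode == "extsize" else t.read_length + ext
        if t.strand == "+":
            start, end = t.five_prime_pos, t.five_prime_pos + length
        else:
            start, end = t.five_prime_pos - length + 1, t.five_prime_pos + 1
        if chrom_lengths is not None:
            if t.chrom not in chrom_lengths:
                raise KeyError(
                    f"chromosome {t.chrom!r} missing from chrom_lengths; "
                    "cannot clip fragment"
                )
            start = max(start, 0)
            end = min(end, chrom_lengths[t.chrom])
        elif start < 0:
            start = 0
        if start < end:
            out.append(GenomicInterval(t.chrom, start, end, t.strand))
    return out


def _depth_arrays(
    fragments: Iterable[GenomicInterval], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Integer per-base depth per chromosome (difference-array pileup)."""
    diffs = {
        chrom: np.zeros(length + 1, dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    for f in fragments:
        d = diffs.get(f.chrom)
        if d is None:
            raise KeyError(f"fragment on unknown chromosome {f.chrom!r}")
        if f.end > len(d) - 1:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} exceeds chromosome "
                f"length {len(d) - 1}"
            )
        d[f.start] += 1
        d[f.end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def pileup(
    fragments: list[GenomicInterval],
    chrom_lengths: dict[str, int],
    cfg: PipelineConfig,
    n_tags_used: Optional[int] = None,
) -> SignalTrack:
    """Binned normalized coverage from extended fragments.

    Per-base depth is multiplied by ``norm_target_reads / n_tags_used``
    and averaged within consecutive ``track_bin`` bp bins.  ``n_tags_used``
    defaults to the fragment count (one fragment per post-dedup tag).
    """
    n = len(fragments) if n_tags_used is None else n_tags_used
    if n == 0:
        raise ValueError("cannot normalize a track built from 0 tags")
    scale = cfg.norm_target_reads / n
    bs = cfg.track_bin
    depth = _depth_arrays(fragments, chrom_lengths)
    values: dict[str, np.ndarray] = {}
    for chrom, arr in depth.items():
        n_bins = -(-len(arr) // bs)
        padded = np.zeros(n_bins * bs, dtype=np.int64)
        padded[: len(arr)] = arr
        values[chrom] = padded.reshape(n_bins, bs).sum(axis=1) * (scale / bs)
    return SignalTrack(bin_size=bs, values=values, n_tags_used=n, scale_factor=scale)


def track_from_tags(
    tags: list[TagAlignment],
    chrom_lengths: dict[str, int],
    cfg: PipelineConfig,
    deduplicate: bool = True,
) -> SignalTrack:
    """Convenience chain: dedup -> extend (clipped) -> pileup."""
    if deduplicate:
        tags = dedup_tags(tags)
    fragments = extend_tags(tags, cfg, chrom_lengths)
    return pileup(fragments, chrom_lengths, cfg, n_tags_used=len(tags))


def write_bedgraph(
    track: SignalTrack, path: Union[str, Path], dense: bool = False
) -> None:
    """Write one line per bin; zero bins are omitted unless ``dense``."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            for j, v in enumerate(vals):
                if v == 0 and not dense:
                    continue
                fh.write(f"{chrom}\t{j * bs}\t{(j + 1) * bs}\t{v:.6g}\n")


def tss_metaprofile(
    tags: list[TagAlignment],
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    cfg: PipelineConfig,
    deduplicate: bool = True,
) -> Metaprofile:
    """Aggregate normalized coverage in 10 bp bins across all TSSs.

    Bin ``j`` covers stranded offsets ``[-flank + j*bin, -flank + (j+1)*
    bin)`` from the TSS; with ``orient_metaprofile_by_strand`` the window
    of a minus-strand gene is read right-to-left so increasing bin index
    is always downstream of the TSS.  Genes whose window does not fit
    inside the chromosome are dropped (and counted in the log).
    """
    if deduplicate:
        tags = dedup_tags(tags)
    if not tags:
        raise ValueError("no tags to profile")
    flank, bs = cfg.metaprofile_flank, cfg.track_bin
    if (2 * flank) % bs:
        raise ValueError("metaprofile window must be a whole number of bins")
    n_bins = 2 * flank // bs
    fragments = extend_tags(tags, cfg, chrom_lengths)
    depth = _depth_arrays(fragments, chrom_lengths)
    scale = cfg.norm_target_reads / len(tags)
    total = np.zeros(n_bins, dtype=float)
    n_used = 0
    n_dropped = 0
    for g in genes:
        arr = depth.get(g.chrom)
        if arr is None:
            n_dropped += 1
            continue
        flip = cfg.orient_metaprofile_by_strand and g.strand == "-"
        if flip:
            lo, hi = g.tss - flank + 1, g.tss + flank + 1
        else:
            lo, hi = g.tss - flank, g.tss + flank
        if lo < 0 or hi > len(arr):
            n_dropped += 1
            continue
        window = arr[lo:hi].astype(float)
        if flip:
            window = window[::-1]
        total += window.reshape(n_bins, bs).mean(axis=1)
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene has a full metaprofile window inside its chromosome")
    if n_dropped:
        log.info("%d genes dropped from metaprofile (truncated window)", n_dropped)
    return Metaprofile(
        bin_size=bs,
        flank=flank,
        values=total * scale / n_used,
        n_tss=n_used,
        n_tags_used=len(tags),
    )
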