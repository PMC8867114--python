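"""Replicate-consensus peak filtering.

Per-replicate peak calls are reduced to a final list in three steps:
removal of peaks touching blacklist regions, an asymmetric p-value
threshold (stringent on the designated best replicate, looser on the
others), and a >=1 bp overlap requirement of each best-replicate peak with
the other replicate(s).  Final peaks keep the best replicate's
coordinates, summits and p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import PipelineConfig
from .intervals import GenomicInterval, IntervalIndex, Peak, PeakSet, TagAlignment


@dataclass
class ConsensusReport:
    """Bookkeeping for one consensus run (counts at each filtering stage)."""

    n_input_per_replicate: dict[str, int] = field(default_factory=dict)
    n_blacklisted: dict[str, int] = field(default_factory=dict)
    n_pass_threshold: dict[str, int] = field(default_factory=dict)
    n_final: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input_per_replicate": self.n_input_per_replicate,
            "n_blacklisted": self.n_blacklisted,
            "n_pass_threshold": self.n_pass_threshold,
            "n_final": self.n_final,
        }


def filter_blacklist(peaks: PeakSet, blacklist: list[GenomicInterval]) -> PeakSet:
    """Drop every peak sharing >=1 bp with any blacklist region."""
    if not blacklist:
        return PeakSet(peaks.name, list(peaks.peaks))
    index = IntervalIndex(blacklist)
    keep = [not index.overlaps_any(p.chrom, p.start, p.end) for p in peaks]
    return peaks.subset(keep)


def threshold_peaks(peaks: PeakSet, p_max: float) -> PeakSet:
    """Keep peaks with p-value <= ``p_max`` (boundary inclusive).

    Peaks carry -log10 p, so the retained set is ``neglog10_p >=
    -log10(p_max)``.
    """
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must lie in (0, 1], got {p_max}")
    cutoff = -math.log10(p_max)
    return peaks.subset([p.neglog10_p >= cutoff for p in peaks])


def consensus_peaks(
    best: PeakSet, others: list[PeakSet], cfg: PipelineConfig
) -> tuple[PeakSet, ConsensusReport]:
    """Retain best-replicate peaks supported by the other replicate(s).

    A best peak is kept when its interval overlaps (>= 1 bp) a peak in
    every other set (``consensus_mode='all'``) or in at least one
    (``'any'``).  Inputs are assumed already blacklist-filtered and
    thresholded (see :func:`consensus_pipeline` for the full chain).
    """
    if not others:
        raise ValueError("consensus requires >=2 replicates (no 'other' sets)")
    indexes = [IntervalIndex(o.intervals()) for o in others]
    require_all = cfg.consensus_mode == "all"
    keep = []
    for p in best:
        hits = (ix.overlaps_any(p.chrom, p.start, p.end) for ix in indexes)
        keep.append(all(hits) if require_all else any(hits))
    final = best.subset(keep, name=f"{best.name}_consensus")
    report = ConsensusReport(
        n_input_per_replicate={s.name: len(s) for s in [best, *others]},
        n_pass_threshold={s.name: len(s) for s in [best, *others]},
        n_final=len(final),
    )
    return final, report


def consensus_pipeline(
    best: PeakSet,
    others: list[PeakSet],
    blacklist: list[GenomicInterval],
    cfg: PipelineConfig,
) -> tuple[PeakSet, ConsensusReport]:
    """Full chain: per-replicate blacklist filter -> asymmetric thresholds
    -> replicate-overlap consensus, with stage counts in the report."""
    if not others:
        raise ValueError("consensus requires >=2 replicates (no 'other' sets)")
    report = ConsensusReport(
        n_input_per_replicate={s.name: len(s) for s in [best, *others]}
    )
    bl_best = filter_blacklist(best, blacklist)
    bl_others = [filter_blacklist(o, blacklist) for o in others]
    report.n_blacklisted = {
        s.name: len(raw) - len(flt)
        for raw, flt, s in zip(
            [best, *others], [bl_best, *bl_others], [best, *others]
        )
    }
    th_best = threshold_peaks(bl_best, cfg.p_best)
    th_others = [threshold_peaks(o, cfg.p_other) for o in bl_others]
    report.n_pass_threshold = {s.name: len(s) for s in [th_best, *th_others]}
    final, _ = consensus_peaks(th_best, th_others, cfg)
    report.n_final = len(final)
    return final, report


def fraction_tags_in_peaks(tags: list[TagAlignment], peaks: PeakSet) -> float:
    """FRiP-style replicate-quality helper: fraction of tag 5' ends inside
    called peaks.  Advisory only — the best replicate is always designated
    by the caller, never auto-selected."""
    if not tags:
        raise ValueError("no tags")
    index = IntervalIndex(peaks.intervals())
    n_in = sum(
        index.overlaps_any(t.chrom, t.five_prime_pos, t.five_prime_pos + 1)
        for t in tags
    )
    return n_in / len(tags)
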