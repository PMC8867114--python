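"""Synthetic datasets with planted, fully known structure.

From a seed and a small config this module generates everything the
pipeline consumes — a random genome, non-overlapping stranded multi-exon
gene models, per-gene binding truth for two factors (A and B), noisy
per-replicate tag alignments and peak calls, a blacklist, and RNA-seq
style count tables — so every downstream stage can be verified offline
against the planted truth.

The emulated regime: two homologous chromatin factors whose binding sites
sit in gene promoters, mostly shared (dual) with a factor-A-exclusive
minority; 2 ChIP replicates of unequal quality per factor plus a
non-enriched input; MACS2-style peak calls with per-replicate p-values,
replicate-specific false peaks and occasional artifact regions; and count
tables in which promoter-bound genes are systematically more highly
expressed than unbound ones.

Every artifact is deterministic given (config, seed): each generation
stage derives its own child generator from ``SeedSequence([seed, stage])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    Peak,
    PeakSet,
    TagAlignment,
    merge_intervals,
    union_exon_length,
)
from . import io as pio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed stage indices for child RNG derivation
_STAGE_GENOME = 0
_STAGE_TRUTH = 1
_STAGE_TAGS_A = 2
_STAGE_TAGS_B = 3
_STAGE_TAGS_INPUT = 4
_STAGE_PEAKS_A = 5
_STAGE_PEAKS_B = 6
_STAGE_COUNTS = 7
_STAGE_BLACKLIST = 8


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass
class SimConfig:
    """Study-condition knobs for the generator (defaults = test conditions).

    Gene placement guarantees >=5.5 kb of clearance between the
    annotation-window footprints of neighboring genes, so planted promoter
    summits can only classify as promoter.
    """

    # genome / annotation
    autosomes: tuple[str, ...] = ("chr1", "chr2")
    sex_chrom: str = "chrY"
    n_genes: int = 200
    n_chry_genes: int = 10  # of n_genes, placed on the sex chromosome
    n_rrna: int = 6  # rRNA-biotype genes (exercise the biotype filter)
    n_short: int = 6  # sub-200 bp genes (exercise the length filter)
    gene_span: tuple[int, int] = (1000, 6000)
    short_span: tuple[int, int] = (100, 180)
    max_exons: int = 4
    min_gap: int = 11000  # keeps +-5 kb windows of neighbors disjoint
    max_gap: int = 16000
    # binding truth
    f_dual: float = 0.30
    f_a_only: float = 0.15
    f_b_only: float = 0.02
    summit_sd: float = 50.0
    promoter_window: tuple[int, int] = (-1000, 500)
    # tags
    background_per_kb: float = 20.0
    enrich_tags_per_site: float = 100.0
    replicate_quality: tuple[float, ...] = (1.0, 0.6)
    duplicate_rate: float = 0.1
    read_length: int = 50
    frag_size: int = 200
    # peak calls
    sensitivities: tuple[float, ...] = (1.0, 0.9)
    false_per_mb: float = 5.0
    peak_halfwidth: int = 150
    true_p_base: float = 2.0
    true_p_exp_mean: float = 3.0
    false_p_range: tuple[float, float] = (1.0, 2.5)
    # blacklist / artifact signal
    n_blacklist: int = 3
    blacklist_size: int = 1000
    n_artifact_sites: int = 2  # strong fake peaks inside blacklist regions
    # expression counts
    mu_unbound: float = 100.0
    mu_bound: float = 400.0  # planted log2 fold change of 2
    dispersion: float = 0.3
    n_expr_replicates: int = 2

    def __post_init__(self) -> None:
        if self.f_dual + self.f_a_only + self.f_b_only > 1:
            raise ValueError("binding fractions must sum to <= 1")
        if not all(0 < s <= 1 for s in self.sensitivities):
            raise ValueError("sensitivities must lie in (0, 1]")
        if self.min_gap < 11000:
            raise ValueError(
                "min_gap < 11 kb lets annotation windows of neighboring "
                "genes collide"
            )


@dataclass
class SimulatedAnnotation:
    """Genome + gene models plus placement bookkeeping."""

    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    genes: list[GeneModel]
    #: intergenic segments >= 5.5 kb away from every gene (safe for noise)
    free_segments: list[GenomicInterval]

    def gtf_text(self) -> str:
        lines = []
        for g in self.genes:
            span = g.span
            attrs = (
                f'gene_id "{g.gene_id}"; gene_type "{g.biotype}"; '
                f'gene_name "{g.gene_id}";'
            )
            lines.append(
                f"{g.chrom}\tsim\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}"
            )
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_type "{g.biotype}";'
            lines.append(
                f"{g.chrom}\tsim\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{tattrs}"
            )
            for e in g.exons:
                lines.append(
                    f"{g.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\t{tattrs}"
                )
        return "\n".join(lines) + "\n"

    def fasta_records(self) -> list[tuple[str, str]]:
        return [(c, self.sequences[c]) for c in sorted(self.sequences)]


@dataclass
class SimulationTruth:
    """Planted ground truth: per-gene membership, summits, regimes."""

    membership: dict[str, str]  # gene_id -> dual | A_only | B_only | none
    summit: dict[str, tuple[str, int]]  # bound gene_id -> (chrom, position)
    replicate_quality: tuple[float, ...]
    sensitivities: tuple[float, ...]

    def sites(self, factor: str) -> list[tuple[str, str, int]]:
        """(gene_id, chrom, summit) of every planted site of a factor."""
        wanted = {"dual", f"{factor}_only"}
        return sorted(
            (g, *self.summit[g])
            for g, m in self.membership.items()
            if m in wanted
        )

    def bound_gene_ids(self, factor: Optional[str] = None) -> set[str]:
        if factor is None:
            return {g for g, m in self.membership.items() if m != "none"}
        wanted = {"dual", f"{factor}_only"}
        return {g for g, m in self.membership.items() if m in wanted}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.membership):
            chrom, pos = self.summit.get(g, ("", -1))
            rows.append((g, self.membership[g], chrom, pos))
        return pd.DataFrame(
            rows, columns=["gene_id", "membership", "summit_chrom", "summit_pos"]
        )


def _draw_exons(
    rng: np.random.Generator, start: int, span: int, max_exons: int
) -> list[tuple[int, int]]:
    """Exon spans (absolute, half-open) tiling a gene: first and last
    segments are exonic; internal cut points alternate exon/intron."""
    k = int(rng.integers(1, max_exons + 1))
    if k == 1 or span < 4 * k * 30:
        return [(start, start + span)]
    for _ in range(20):
        cuts = np.sort(rng.choice(np.arange(1, span), size=2 * (k - 1), replace=False))
        bounds = [0, *cuts.tolist(), span]
        segs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        exons = segs[0::2]
        if min(b - a for a, b in segs) >= 30 and sum(b - a for a, b in exons) >= 200:
            return [(start + a, start + b) for a, b in exons]
    return [(start, start + span)]


def simulate_annotation(cfg: SimConfig, seed: int) -> SimulatedAnnotation:
    """Random genome and non-overlapping gene models.

    Genes are laid out left to right per chromosome with gaps drawn from
    ``[min_gap, max_gap]``; special genes (rRNA biotype, sub-200 bp) are
    interspersed deterministically to exercise the RNA-seq filters.
    """
    rng = _rng(seed, _STAGE_GENOME)
    chroms = [*cfg.autosomes, cfg.sex_chrom]
    n_auto = cfg.n_genes - cfg.n_chry_genes
    if n_auto < 0:
        raise ValueError("n_chry_genes exceeds n_genes")
    # per-gene plan: (chrom, is_short, biotype)
    plan: list[tuple[str, bool, str]] = []
    for i in range(n_auto):
        plan.append((cfg.autosomes[i % len(cfg.autosomes)], False, "protein_coding"))
    plan += [(cfg.sex_chrom, False, "protein_coding")] * cfg.n_chry_genes
    if cfg.n_rrna + cfg.n_short > n_auto:
        raise ValueError("more special genes requested than autosomal genes")
    special = rng.choice(n_auto, size=cfg.n_rrna + cfg.n_short, replace=False)
    for j in special[: cfg.n_rrna]:
        chrom, _, _ = plan[j]
        plan[j] = (chrom, False, "rRNA")
    for j in special[cfg.n_rrna :]:
        chrom, _, bt = plan[j]
        plan[j] = (chrom, True, bt)

    genes: list[GeneModel] = []
    free: list[GenomicInterval] = []
    chrom_lengths: dict[str, int] = {}
    margin = 5500  # annotation-window footprint half-extent + slack
    gid = 0
    for chrom in chroms:
        entries = [p for p in plan if p[0] == chrom]
        cursor = cfg.min_gap
        prev_end: Optional[int] = None
        for _, is_short, biotype in entries:
            lo, hi = cfg.short_span if is_short else cfg.gene_span
            span = int(rng.integers(lo, hi + 1))
            gap = int(rng.integers(cfg.min_gap, cfg.max_gap + 1))
            start = cursor
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            exon_spans = (
                [(start, end)]
                if is_short
                else _draw_exons(rng, start, span, cfg.max_exons)
            )
            exons = tuple(
                GenomicInterval(chrom, a, b, strand) for a, b in exon_spans
            )
            tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"SIMG{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    exons=exons,
                    biotype=biotype,
                    union_exon_length=union_exon_length(exons),
                )
            )
            if prev_end is not None and start - margin > prev_end + margin:
                free.append(GenomicInterval(chrom, prev_end + margin, start - margin))
            prev_end = end
            cursor = end + gap
        chrom_lengths[chrom] = cursor + cfg.min_gap
        if prev_end is not None and chrom_lengths[chrom] - margin > prev_end + margin:
            free.append(
                GenomicInterval(chrom, prev_end + margin, chrom_lengths[chrom] - margin)
            )
    sequences = {
        chrom: _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        for chrom, length in chrom_lengths.items()
    }
    return SimulatedAnnotation(chrom_lengths, sequences, genes, free)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer group sizes: floor quotas, then distribute the remainder of
    the floored total to the largest fractional parts (ties by order)."""
    quotas = [f * n for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    leftover = int(np.floor(sum(quotas))) - sum(base)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - base[i]), i)
    )
    for i in order[:leftover]:
        base[i] += 1
    return base


def simulate_truth(
    genes: list[GeneModel], cfg: SimConfig, seed: int
) -> SimulationTruth:
    """Plant binding membership and promoter summits on eligible genes.

    Eligible = non-rRNA, non-chrY, union-exon length >= 200 bp; membership
    group sizes follow floor + largest-remainder rounding of the config
    fractions; each bound gene gets one summit at TSS + round(N(0, 50 bp))
    clipped into the promoter window.
    """
    rng = _rng(seed, _STAGE_TRUTH)
    eligible = [
        g
        for g in genes
        if "rRNA" not in g.biotype
        and g.chrom != cfg.sex_chrom
        and g.union_exon_length >= 200
    ]
    n_dual, n_a, n_b = _largest_remainder(
        len(eligible), (cfg.f_dual, cfg.f_a_only, cfg.f_b_only)
    )
    order = rng.permutation(len(eligible))
    membership: dict[str, str] = {g.gene_id: "none" for g in genes}
    labels = ["dual"] * n_dual + ["A_only"] * n_a + ["B_only"] * n_b
    chosen = [eligible[i] for i in order[: len(labels)]]
    summit: dict[str, tuple[str, int]] = {}
    lo, hi = cfg.promoter_window
    for g, label in zip(chosen, labels):
        membership[g.gene_id] = label
        offset = int(np.clip(round(rng.normal(0.0, cfg.summit_sd)), lo, hi - 1))
        summit[g.gene_id] = (g.chrom, g.to_genomic(offset, g.tss))
    return SimulationTruth(
        membership=membership,
        summit=summit,
        replicate_quality=cfg.replicate_quality,
        sensitivities=cfg.sensitivities,
    )


def _background_tags(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    cfg: SimConfig,
) -> list[TagAlignment]:
    tags: list[TagAlignment] = []
    rl = cfg.read_length
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n = rng.poisson(cfg.background_per_kb * length / 1000.0)
        pos = rng.integers(0, length, size=n)
        minus = rng.random(n) < 0.5
        # keep whole reads inside the chromosome
        pos = np.where(minus, np.clip(pos, rl - 1, length - 1), np.clip(pos, 0, length - rl))
        for p, m in zip(pos.tolist(), minus.tolist()):
            tags.append(TagAlignment(chrom, p, "-" if m else "+", rl))
    return tags


def _inject_duplicates(
    rng: np.random.Generator, tags: list[TagAlignment], rate: float
) -> list[TagAlignment]:
    if rate <= 0 or not tags:
        return tags
    n_extra = int(round(rate / (1.0 - rate) * len(tags)))
    idx = rng.integers(0, len(tags), size=n_extra)
    return tags + [tags[i] for i in idx.tolist()]


def simulate_tags(
    truth: SimulationTruth,
    annotation: SimulatedAnnotation,
    cfg: SimConfig,
    seed: int,
    factor: str = "A",
) -> list[list[TagAlignment]]:
    """Per-replicate ChIP tag lists for one factor.

    Each replicate holds uniform background plus enrichment tags whose
    extended fragments cover the planted summits (plus-strand 5' ends at
    ``summit - U{0..frag_size-1}``, minus-strand mirrored), scaled by the
    replicate quality multiplier, with PCR duplicates injected at the
    configured rate.
    """
    stage = _STAGE_TAGS_A if factor == "A" else _STAGE_TAGS_B
    rng = _rng(seed, stage)
    sites = truth.sites(factor)
    rl, fs = cfg.read_length, cfg.frag_size
    replicates: list[list[TagAlignment]] = []
    for quality in cfg.replicate_quality:
        tags = _background_tags(rng, annotation.chrom_lengths, cfg)
        for _, chrom, summit in sites:
            length = annotation.chrom_lengths[chrom]
            n = rng.poisson(cfg.enrich_tags_per_site * quality)
            offsets = rng.integers(0, fs, size=n)
            minus = rng.random(n) < 0.5
            pos = np.where(minus, summit + offsets, summit - offsets)
            pos = np.where(
                minus, np.clip(pos, rl - 1, length - 1), np.clip(pos, 0, length - rl)
            )
            for p, m in zip(pos.tolist(), minus.tolist()):
                tags.append(TagAlignment(chrom, int(p), "-" if m else "+", rl))
        replicates.append(_inject_duplicates(rng, tags, cfg.duplicate_rate))
    return replicates


def simulate_input_tags(
    annotation: SimulatedAnnotation, cfg: SimConfig, seed: int
) -> list[TagAlignment]:
    """Non-enriched control sample: background only (plus duplicates)."""
    rng = _rng(seed, _STAGE_TAGS_INPUT)
    tags = _background_tags(rng, annotation.chrom_lengths, cfg)
    return _inject_duplicates(rng, tags, cfg.duplicate_rate)


def simulate_blacklist(
    annotation: SimulatedAnnotation, cfg: SimConfig, seed: int
) -> tuple[list[GenomicInterval], list[tuple[str, int]]]:
    """Blacklist regions in intergenic space, plus artifact summits inside
    them that will produce strong fake peaks in every replicate."""
    rng = _rng(seed, _STAGE_BLACKLIST)
    regions = _sample_free_positions(
        rng, annotation.free_segments, cfg.n_blacklist, cfg.blacklist_size
    )
    artifacts: list[tuple[str, int]] = []
    for i in range(cfg.n_artifact_sites):
        region = regions[i % len(regions)]
        artifacts.append((region.chrom, (region.start + region.end) // 2))
    return regions, artifacts


def _sample_free_positions(
    rng: np.random.Generator,
    free: list[GenomicInterval],
    n: int,
    width: int,
) -> list[GenomicInterval]:
    """Uniformly sample ``n`` width-bp spans from the free intergenic
    segments (segment chosen proportional to usable length)."""
    usable = [s for s in free if len(s) > width]
    if not usable:
        raise ValueError("no intergenic segment wide enough")
    weights = np.array([len(s) - width for s in usable], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        seg = usable[int(rng.choice(len(usable), p=weights))]
        start = int(rng.integers(seg.start, seg.end - width))
        out.append(GenomicInterval(seg.chrom, start, start + width))
    return out


def simulate_replicate_peaks(
    truth: SimulationTruth,
    annotation: SimulatedAnnotation,
    cfg: SimConfig,
    seed: int,
    factor: str = "A",
    artifact_summits: Optional[list[tuple[str, int]]] = None,
) -> list[PeakSet]:
    """MACS2-style per-replicate peak calls for one factor.

    True sites appear in replicate r with probability ``sensitivities[r]``
    as ``[summit-150, summit+150)`` peaks with -log10 p = 2 + Exp(mean 3);
    false peaks land uniformly in intergenic space with -log10 p ~
    U(1.0, 2.5); artifact summits (inside blacklist regions) yield strong
    peaks in every replicate.
    """
    stage = _STAGE_PEAKS_A if factor == "A" else _STAGE_PEAKS_B
    rng = _rng(seed, stage)
    sites = truth.sites(factor)
    hw = cfg.peak_halfwidth
    genome_mb = sum(annotation.chrom_lengths.values()) / 1e6
    out: list[PeakSet] = []
    for r, sens in enumerate(cfg.sensitivities):
        source = f"{factor}_rep{r + 1}"
        peaks: list[Peak] = []
        for gene_id, chrom, summit in sites:
            if rng.random() >= sens:
                continue
            p = cfg.true_p_base + rng.exponential(cfg.true_p_exp_mean)
            peaks.append(
                Peak(
                    GenomicInterval(chrom, summit - hw, summit + hw),
                    summit_offset=hw,
                    neglog10_p=float(p),
                    source_id=source,
                    name=f"{source}_{gene_id}",
                )
            )
        for j, (chrom, summit) in enumerate(artifact_summits or []):
            p = cfg.true_p_base + rng.exponential(cfg.true_p_exp_mean)
            peaks.append(
                Peak(
                    GenomicInterval(chrom, summit - hw, summit + hw),
                    summit_offset=hw,
                    neglog10_p=float(p),
                    source_id=source,
                    name=f"{source}_artifact{j}",
                )
            )
        n_false = rng.poisson(cfg.false_per_mb * genome_mb)
        false_spans = _sample_free_positions(
            rng, annotation.free_segments, n_false, 2 * hw
        )
        for j, span in enumerate(false_spans):
            peaks.append(
                Peak(
                    span,
                    summit_offset=hw,
                    neglog10_p=float(rng.uniform(*cfg.false_p_range)),
                    source_id=source,
                    name=f"{source}_false{j}",
                )
            )
        out.append(PeakSet(source, peaks))
    return out


def simulate_counts(
    truth: SimulationTruth,
    genes: list[GeneModel],
    cfg: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Negative-binomial fragment counts, higher for promoter-bound genes.

    Per gene the mean is ``mu_bound`` (any planted binding) or
    ``mu_unbound``, scaled by union-exon length / 1 kb; the dispersion is
    the NB alpha (variance = mu + alpha*mu^2), with the alpha -> 0 limit
    falling back to Poisson.
    """
    rng = _rng(seed, _STAGE_COUNTS)
    bound = truth.bound_gene_ids()
    mus = np.array(
        [
            (cfg.mu_bound if g.gene_id in bound else cfg.mu_unbound)
            * g.union_exon_length
            / 1000.0
            for g in genes
        ]
    )
    cols = {}
    for r in range(cfg.n_expr_replicates):
        if cfg.dispersion <= 1e-12:
            draws = rng.poisson(mus)
        else:
            shape = 1.0 / cfg.dispersion
            draws = rng.negative_binomial(shape, shape / (shape + mus))
        cols[f"rep{r + 1}"] = draws
    return pd.DataFrame(cols, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


@dataclass
class SimulatedDataset:
    """Everything one seeded simulation produced, in memory."""

    cfg: SimConfig
    seed: int
    annotation: SimulatedAnnotation
    truth: SimulationTruth
    blacklist: list[GenomicInterval]
    tags: dict[str, list[list[TagAlignment]]]  # factor -> per-replicate
    input_tags: list[TagAlignment]
    peaks: dict[str, list[PeakSet]]  # factor -> per-replicate
    counts: pd.DataFrame

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write the complete dataset as plain-text standard formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fa"
        pio.write_fasta(self.annotation.fasta_records(), paths["genome"])
        paths["gtf"] = outdir / "genes.gtf"
        paths["gtf"].write_text(self.annotation.gtf_text())
        paths["blacklist"] = outdir / "blacklist.bed"
        pio.write_bed(self.blacklist, paths["blacklist"])
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        for factor, replicate_sets in self.peaks.items():
            for i, ps in enumerate(replicate_sets):
                key = f"peaks_{factor}_rep{i + 1}"
                paths[key] = outdir / f"{factor}_rep{i + 1}.narrowPeak"
                pio.write_narrowpeak(ps, paths[key])
        for factor, replicate_tags in self.tags.items():
            for i, tags in enumerate(replicate_tags):
                key = f"tags_{factor}_rep{i + 1}"
                paths[key] = outdir / f"{factor}_rep{i + 1}.tagAlign.bed"
                pio.write_tagalign(tags, paths[key])
        paths["tags_input"] = outdir / "input.tagAlign.bed"
        pio.write_tagalign(self.input_tags, paths["tags_input"])
        paths["counts"] = outdir / "counts.tsv"
        self.counts.to_csv(paths["counts"], sep="\t")
        return paths


def simulate_dataset(
    cfg: Optional[SimConfig] = None,
    seed: int = 0,
    with_tags: bool = True,
) -> SimulatedDataset:
    """Run every generation stage for one (config, seed) pair."""
    cfg = cfg or SimConfig()
    annotation = simulate_annotation(cfg, seed)
    truth = simulate_truth(annotation.genes, cfg, seed)
    blacklist, artifacts = simulate_blacklist(annotation, cfg, seed)
    peaks = {
        factor: simulate_replicate_peaks(
            truth, annotation, cfg, seed, factor, artifact_summits=artifacts
        )
        for factor in ("A", "B")
    }
    if with_tags:
        tags = {
            factor: simulate_tags(truth, annotation, cfg, seed, factor)
            for factor in ("A", "B")
        }
        input_tags = simulate_input_tags(annotation, cfg, seed)
    else:
        tags, input_tags = {"A": [], "B": []}, []
    counts = simulate_counts(truth, annotation.genes, cfg, seed)
    return SimulatedDataset(
        cfg=cfg,
        seed=seed,
        annotation=annotation,
        truth=truth,
        blacklist=blacklist,
        tags=tags,
        input_tags=input_tags,
        peaks=peaks,
        counts=counts,
    )


def evaluate_consensus(
    final: PeakSet, truth: SimulationTruth, factor: str, halfwidth: int = 150
) -> dict[str, float]:
    """Recall/precision of a final peak list against the planted sites.

    A planted site counts as recovered when its ``[summit-halfwidth,
    summit+halfwidth)`` window overlaps a final peak; a final peak counts
    as true when it overlaps any planted-site window.
    """
    sites = truth.sites(factor)
    site_index = IntervalIndex(
        GenomicInterval(chrom, max(0, s - halfwidth), s + halfwidth)
        for _, chrom, s in sites
    )
    final_index = IntervalIndex(final.intervals())
    n_rec = sum(
        final_index.overlaps_any(chrom, max(0, s - halfwidth), s + halfwidth)
        for _, chrom, s in sites
    )
    n_true_peaks = sum(
        site_index.overlaps_any(p.chrom, p.start, p.end) for p in final
    )
    return {
        "n_sites": len(sites),
        "n_final": len(final),
        "recall": n_rec / len(sites) if sites else float("nan"),
        "precision": n_true_peaks / len(final) if len(final) else float("nan"),
    }
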