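# Methods

This note documents the models, conventions and design choices behind
`peakscape`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate and overlap conventions

All internal coordinates are 0-based half-open (BED convention); GTF
input (1-based inclusive) is converted at the I/O boundary. "Overlap"
always means at least one shared base: `a.start < b.end and b.start <
a.end`. Adjacent intervals share no base and are never merged — the merge
operation chains intervals connected by ≥ 1 bp overlaps and is idempotent.
Chromosome names are matched by exact string equality; a validation
helper warns when two inputs have disjoint chromosome namespaces (the
classic `chr1` vs `1` failure), rather than silently annotating nothing.

The 5′ position of a minus-strand BED record `[start, end)` is `end − 1`.
This matters because every signal operation anchors on the 5′ end: a
minus-strand tag extends 3′-ward to `[p − E + 1, p + 1)`.

## Replicate consensus

The consensus model assumes replicates of unequal quality: the
best-signal replicate (designated by the caller; a FRiP-style helper
reports per-replicate fraction-of-tags-in-peaks to guide the choice but
never auto-selects) is thresholded at p ≤ 0.01 and the others at
p ≤ 0.05, after per-replicate blacklist removal. A best peak survives
iff it overlaps peaks in the other replicate(s); with more than two
replicates the default requires support from *every* other replicate
(`consensus_mode="all"`), with `"any"` available — for two replicates the
modes coincide. Thresholds are boundary-inclusive on the −log₁₀ p scale
(−log₁₀ p = 2.0 passes p ≤ 0.01). Blacklist filtering, thresholding and
consensus commute as filters on the best set, which a test asserts; the
order used (blacklist → threshold → consensus) follows the natural
processing narrative and reports counts per stage.

## Annotation

Each peak is reduced to one anchor base — the reported summit, else
`floor((start+end)/2)` — so that every peak receives exactly one
category. The seven categories are defined by half-open windows in
stranded gene coordinates (offset 0 at the anchor, positive downstream):

| category | window |
|---|---|
| promoter | [TSS−1000, TSS+500) |
| upstream | [TSS−5000, TSS−1000) |
| TES | [TES−500, TES+1000) |
| downstream | [TES+1000, TES+5000) |
| exon / intron | anchor in gene body, in / not in an exon |
| intergenic | anything else |

For short genes these windows overlap; precedence promoter > TES >
upstream > downstream > exon > intron makes the classification a
partition. Genes are modeled at gene level: all transcripts collapsed,
TSS = 5′-most transcribed base over all exons, exon set = union of all
transcript exons (which TSS a multi-transcript gene "really" uses is not
derivable from a gene-level analysis; the gene 5′ end is the default).
Nearest-TSS ties are broken by smaller |stranded distance| then
lexicographically smaller gene id, for run-to-run determinism.

## Signal tracks and metaprofiles

Tags are deduplicated to one copy per (chromosome, 5′ position, strand) —
the strand is part of the key because opposite-strand tags at one
position are distinct ligation events — then replaced by `extsize` = 200
bp fragments anchored at the 5′ end. "Extend by 200 bp to its 3′ end" is
implemented with MACS2 `--extsize` semantics (the read becomes a 200 bp
fragment); the literal alternative (append 200 bp past the 3′ terminus,
giving read_length + 200 fragments) is available as
`extension_mode="append"`. Per-base depth is scaled by
`norm_target_reads / n_tags` (default 10 M) and averaged in 10 bp bins;
positions past the chromosome end count as zero so every bin averages
over exactly `bin_size` bases, which makes the mass identity exact: with
no boundary clipping, Σ(bin value · bin size) = extsize ·
norm_target_reads to machine precision. bedGraph output omits zero bins
unless `dense=True`.

Metaprofiles average the same normalized per-base signal over
[TSS−2500, TSS+2500) in 10 bp bins across all genes whose window fits
inside the chromosome (truncated windows are dropped and counted).
Minus-strand windows are read right-to-left by default so increasing bin
index is always downstream; the flag exists because some published
profiles are unoriented. All annotated genes are profiled by default;
callers can pass any gene subset.

## Venn overlap

Peaks of 2–3 sets are pooled and merged with ≥ 1 bp chaining; a merged
region's membership is the set of sources that contributed ≥ 1
overlapping peak. Counts are of merged regions, not original peaks — a
chain of several peaks from one set counts once — so the result carries
the input peak counts alongside to avoid misreading.

## Expression stratification

Genes with union-exon length < 200 bp, biotypes containing "rRNA" (which
also catches `rRNA_pseudogene`; configurable) or on chrY are removed
first; library sizes for FPKM are computed over the retained genes (the
pre-filter alternative is a flag). FPKM uses union-exon length, per
replicate, and replicates are averaged on the FPKM scale (not the count
scale). A gene is "bound" when a final peak overlaps its promoter window
[TSS−1000, TSS+500) by ≥ 1 bp — a windowed definition rather than "the
peak's assigned gene", because a peak can bind one gene's promoter while
being nearest to a neighbor's TSS; the assigned-category definition is
available via `binding_def`. Groups nonbound / dual / A_only / B_only
(plus `excluded` for filtered genes) partition the gene universe.

Group comparisons use a two-sided Welch (unequal-variance) t test on
log₂(FPKM_mean + 1). FPKM is heavy-tailed, so the log transform and the
unequal-variance form are the robust defaults; raw-scale and
pooled-variance variants are config options. The test's calibration is
checked empirically: under a null simulation the type-I error at
α = 0.05 is within 0.05 ± 0.02 over 1000 seeded runs, and Welch p agrees
with a 10 000-permutation oracle on small groups.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Genome/annotation** — 3 chromosomes (two autosomes + a small chrY),
  200 genes by default, spans 1–6 kb, 1–4 exons, intergenic gaps of
  11–16 kb so that the ±5 kb annotation windows of neighbors cannot
  collide and planted promoter summits classify as promoter by
  construction; a few rRNA-biotype and sub-200 bp genes exercise the
  RNA-seq filters. Sequence is i.i.d. ACGT.
* **Binding truth** — eligible genes are assigned dual / A-only / B-only
  memberships at fractions 0.30 / 0.15 / 0.02 (a dominant-overlap
  structure with an A-exclusive minority), with group sizes fixed by
  floor + largest-remainder rounding; each bound gene gets one summit at
  TSS + round(N(0, 50 bp)) clipped into the promoter window.
* **Tags** — uniform background at 20 tags/kb per sample (the coverage
  scale of a few-tens-of-millions-read library on a mammalian genome),
  ~100 enrichment tags per site scaled by replicate quality multipliers
  (1.0, 0.6), positioned so the 200 bp extended fragment always covers
  the summit; PCR duplicates injected at rate 0.1; the input sample is
  background only. Read length 50 bp.
* **Peak calls** — simulated directly rather than by running a peak
  caller: consensus logic is what needs testing and direct simulation
  gives exact truth labels. True sites appear in replicate r with
  probability (1.0, 0.9), as ±150 bp peaks with −log₁₀ p = 2 + Exp(3);
  false peaks land in deep intergenic space at 5/Mb with −log₁₀ p ~
  U(1, 2.5); two artifact summits inside the 3 blacklist regions produce
  strong peaks in every replicate (removed only by the blacklist
  filter).
* **Counts** — negative binomial with dispersion 0.3, mean 100 (unbound)
  vs 400 (bound) scaled by union-exon length / 1 kb: a planted log₂ fold
  change of 2, two replicates.

Every stage derives its RNG from `SeedSequence([seed, stage])`, so the
whole dataset — and the full downstream analysis — is byte-identical
across runs at a fixed (config, seed).

**What the simulation does not emulate:** realistic sequence composition,
mappability or GC bias, paired-end fragments, transcript-level isoform
structure, chromatin-state-dependent background, or correlated replicate
noise. Passing tests therefore demonstrate the correctness of the
implemented arithmetic and logic under the stated generative model, not
robustness to those real-data artifacts.

A consequence worth stating explicitly: with other-replicate detection
sensitivity 0.9, the overlap consensus necessarily loses the ~10% of
sites the weaker replicate fails to call, so planted-site recall
concentrates near 0.90 (0.925 at seed 7), Venn "dual" counts reflect
sites recovered by *both* factors' consensus (~0.81 of planted duals),
and binding-group labels agree with truth only for genes whose sites
survived. The property tests assert the pipeline-faithful form of these
statements — outputs exactly consistent with what the replicate peak
calls contain — since detection losses occur upstream of the pipeline.

## Problem sizes

Defaults were chosen so a full simulation plus analysis runs in seconds
on one core: ~200 genes on a ~7 Mb genome, ~70 k tags per sample, ~100
peaks per replicate, 1000 null-calibration runs and 200 power runs for
the expression test, and oracle checks on ≤ 100 kb instances. All sizes
scale through `SimConfig`.
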