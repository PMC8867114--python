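"""The synthetic-data generator: determinism, planted structure, regimes."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from peakscape import (
    PipelineConfig,
    dedup_tags,
    read_gtf_genes,
)
from peakscape.simulate import (
    SimConfig,
    _largest_remainder,
    simulate_annotation,
    simulate_counts,
    simulate_dataset,
    simulate_input_tags,
    simulate_replicate_peaks,
    simulate_tags,
    simulate_truth,
)

SMALL = SimConfig(n_genes=60, n_chry_genes=4, n_rrna=2, n_short=2)


class TestAnnotationGeneration:
    def test_deterministic_per_seed(self):
        a = simulate_annotation(SMALL, seed=7)
        b = simulate_annotation(SMALL, seed=7)
        assert a.gtf_text() == b.gtf_text()
        assert a.sequences == b.sequences
        c = simulate_annotation(SMALL, seed=8)
        assert a.gtf_text() != c.gtf_text()

    def test_no_genes_yields_empty_gtf(self):
        cfg = SimConfig(n_genes=0, n_chry_genes=0, n_rrna=0, n_short=0)
        ann = simulate_annotation(cfg, seed=1)
        assert ann.genes == [] and ann.gtf_text() == "\n"

    def test_gtf_round_trip_preserves_gene_models(self, tmp_path):
        ann = simulate_annotation(SMALL, seed=3)
        p = tmp_path / "genes.gtf"
        p.write_text(ann.gtf_text())
        reloaded = {g.gene_id: g for g in read_gtf_genes(p)}
        assert len(reloaded) == len(ann.genes)
        for g in ann.genes:
            r = reloaded[g.gene_id]
            assert (r.tss, r.tes, r.strand, r.biotype) == (g.tss, g.tes, g.strand, g.biotype)
            assert r.union_exon_length == g.union_exon_length
            span = r.span
            assert span.end - span.start >= r.union_exon_length

    def test_genes_do_not_overlap_and_keep_clearance(self):
        ann = simulate_annotation(SMALL, seed=5)
        by_chrom: dict[str, list] = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort(key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                assert b.start - a.end >= 11_000

    def test_special_genes_present(self):
        ann = simulate_annotation(SMALL, seed=5)
        assert sum(g.biotype == "rRNA" for g in ann.genes) == 2
        assert sum(g.union_exon_length < 200 for g in ann.genes) == 2
        assert sum(g.chrom == "chrY" for g in ann.genes) == 4


class TestTruth:
    def test_largest_remainder_rounding(self):
        assert _largest_remainder(200, (0.30, 0.15, 0.02)) == [60, 30, 4]
        # 178 eligible: quotas 53.4/26.7/3.56 floor to 82; floor of the
        # summed quota (83) leaves one seat for the largest remainder (0.7)
        assert _largest_remainder(178, (0.30, 0.15, 0.02)) == [53, 27, 3]
        assert sum(_largest_remainder(178, (0.30, 0.15, 0.02))) == int(
            np.floor(178 * 0.47)
        )

    def test_default_fractions_on_200_eligible_genes(self):
        # 212 genes minus 6 chrY, 3 rRNA, 3 short = 200 eligible
        cfg = SimConfig(n_genes=212, n_chry_genes=6, n_rrna=3, n_short=3)
        ann = simulate_annotation(cfg, seed=7)
        truth = simulate_truth(ann.genes, cfg, seed=7)
        counts = {k: 0 for k in ("dual", "A_only", "B_only", "none")}
        for m in truth.membership.values():
            counts[m] += 1
        assert counts["dual"] == 60
        assert counts["A_only"] == 30
        assert counts["B_only"] == 4

    def test_every_eligible_gene_dual_when_fraction_one(self):
        cfg = SimConfig(
            n_genes=40, n_chry_genes=2, n_rrna=1, n_short=1,
            f_dual=1.0, f_a_only=0.0, f_b_only=0.0,
        )
        ann = simulate_annotation(cfg, seed=2)
        truth = simulate_truth(ann.genes, cfg, seed=2)
        eligible = {
            g.gene_id
            for g in ann.genes
            if g.biotype != "rRNA" and g.chrom != "chrY" and g.union_exon_length >= 200
        }
        assert truth.bound_gene_ids() == eligible
        assert all(truth.membership[g] == "dual" for g in eligible)

    def test_fractions_above_one_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(f_dual=0.8, f_a_only=0.3)

    def test_summits_lie_inside_promoter_windows(self, sim):
        genes = {g.gene_id: g for g in sim.annotation.genes}
        lo, hi = sim.cfg.promoter_window
        for gid, (chrom, pos) in sim.truth.summit.items():
            g = genes[gid]
            offset = g.stranded_offset(pos, g.tss)
            assert g.chrom == chrom
            assert lo <= offset < hi


class TestTags:
    def test_zero_enrichment_makes_chip_match_input(self):
        cfg = SimConfig(n_genes=60, n_chry_genes=4, enrich_tags_per_site=0.0, duplicate_rate=0.0)
        ann = simulate_annotation(cfg, seed=7)
        truth = simulate_truth(ann.genes, cfg, seed=7)
        chip = simulate_tags(truth, ann, cfg, seed=7, factor="A")[0]
        inp = simulate_input_tags(ann, cfg, seed=7)
        pos_chip = [t.five_prime_pos for t in chip if t.chrom == "chr1"]
        pos_inp = [t.five_prime_pos for t in inp if t.chrom == "chr1"]
        ks = stats.ks_2samp(pos_chip, pos_inp)
        assert ks.pvalue > 0.01

    def test_duplicate_rate_half_removes_about_half(self):
        cfg = SimConfig(n_genes=30, n_chry_genes=2, duplicate_rate=0.5)
        ann = simulate_annotation(cfg, seed=11)
        truth = simulate_truth(ann.genes, cfg, seed=11)
        tags = simulate_tags(truth, ann, cfg, seed=11, factor="A")[0]
        kept = len(dedup_tags(tags)) / len(tags)
        # duplicates are half the library; natural collisions shave a bit more
        assert 0.42 <= kept <= 0.55

    def test_enrichment_fragments_cover_the_summit(self, sim):
        cfg = sim.cfg
        # every enrichment tag was drawn so its extended fragment covers
        # its source summit; verify coverage at summits far exceeds background
        from peakscape import PipelineConfig, track_from_tags

        track = track_from_tags(
            sim.tags["A"][0], sim.annotation.chrom_lengths, PipelineConfig()
        )
        vals = []
        for _, chrom, s in sim.truth.sites("A"):
            vals.append(track.values[chrom][s // 10])
        background = np.median(np.concatenate(list(track.values.values())))
        assert np.median(vals) > 10 * background


class TestReplicatePeaks:
    def test_perfect_sensitivity_no_noise_reproduces_truth(self):
        cfg = SimConfig(
            n_genes=60, n_chry_genes=4, sensitivities=(1.0, 1.0),
            false_per_mb=0.0, n_artifact_sites=0,
        )
        ann = simulate_annotation(cfg, seed=9)
        truth = simulate_truth(ann.genes, cfg, seed=9)
        reps = simulate_replicate_peaks(truth, ann, cfg, seed=9, factor="A")
        sites = {(chrom, s) for _, chrom, s in truth.sites("A")}
        for ps in reps:
            got = {(p.chrom, p.summit_pos) for p in ps}
            assert got == sites

    def test_peak_p_values_respect_generating_regimes(self, sim):
        for ps in sim.peaks["A"]:
            for p in ps:
                if "false" in p.name:
                    assert 1.0 <= p.neglog10_p <= 2.5
                else:
                    assert p.neglog10_p >= 2.0

    def test_capped_false_p_values_never_pass_best_threshold(self):
        from peakscape import threshold_peaks

        cfg = SimConfig(n_genes=60, n_chry_genes=4, false_p_range=(1.0, 1.9))
        ann = simulate_annotation(cfg, seed=13)
        truth = simulate_truth(ann.genes, cfg, seed=13)
        (rep1, _) = simulate_replicate_peaks(truth, ann, cfg, seed=13, factor="A")
        surviving = threshold_peaks(rep1, 0.01)
        assert all("false" not in p.name for p in surviving)


class TestCounts:
    def test_bound_genes_systematically_higher(self, sim):
        counts = sim.counts
        per_kb = counts.mean(axis=1) / np.array(
            [g.union_exon_length / 1000 for g in sim.annotation.genes]
        )
        bound = sim.truth.bound_gene_ids()
        mask = counts.index.isin(bound)
        assert per_kb[mask].mean() > 3 * per_kb[~mask].mean()

    def test_zero_dispersion_limit_is_poisson(self):
        cfg = SimConfig(n_genes=60, n_chry_genes=4, dispersion=0.0)
        ann = simulate_annotation(cfg, seed=21)
        truth = simulate_truth(ann.genes, cfg, seed=21)
        draws = []
        for s in range(200):
            c = simulate_counts(truth, ann.genes, cfg, seed=1_000 + s)
            draws.append(c.iloc[0, 0])
        draws = np.array(draws, dtype=float)
        # variance/mean ratio ~ 1 for Poisson
        assert 0.75 < draws.var() / draws.mean() < 1.3


class TestEndToEnd:
    def test_dataset_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(n_genes=40, n_chry_genes=2, n_rrna=1, n_short=1)
        d1 = simulate_dataset(cfg, seed=7).write(tmp_path / "run1")
        d2 = simulate_dataset(cfg, seed=7).write(tmp_path / "run2")
        assert set(d1) == set(d2)
        for key in d1:
            assert filecmp.cmp(d1[key], d2[key], shallow=False), key

    def test_venn_dual_count_matches_surviving_sites(self, sim, final_peaks, cfg):
        """Dual merged regions equal planted dual genes whose site survived
        consensus in BOTH factors (the pipeline adds or loses nothing)."""
        from peakscape import venn_counts
        from peakscape.intervals import IntervalIndex

        finalA, finalB = final_peaks["A"][0], final_peaks["B"][0]
        v = venn_counts([finalA, finalB])
        surv = {}
        for factor, final in (("A", finalA), ("B", finalB)):
            idx = IntervalIndex(final.intervals())
            surv[factor] = {
                gid
                for gid, chrom, s in sim.truth.sites(factor)
                if idx.overlaps_any(chrom, s - 150, s + 150)
            }
        expected_dual = len(surv["A"] & surv["B"])
        assert v.count("A_rep1_consensus", "B_rep1_consensus") == expected_dual
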