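"""Gene filters, FPKM arithmetic, binding groups and the group t test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peakscape import (
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    PipelineConfig,
    assign_groups,
    bound_genes,
    compare_groups,
    filter_genes,
    fpkm,
    read_counts_table,
)
from peakscape.intervals import overlaps, stranded_window

cfg = PipelineConfig()


def gene(gene_id, tss=10_000, length=2_000, strand="+", chrom="chr1", biotype="protein_coding"):
    if strand == "+":
        tes = tss + length
        exons = (GenomicInterval(chrom, tss, tes + 1, strand),)
    else:
        tes = tss - length
        exons = (GenomicInterval(chrom, tes, tss + 1, strand),)
    return GeneModel(
        gene_id, chrom, strand, tss, tes, exons,
        biotype=biotype, union_exon_length=length + 1,
    )


class TestFilterGenes:
    def test_all_three_rules(self):
        genes = [
            gene("ok", 10_000, 5_000),
            gene("short", 30_000, 150),
            gene("ribo", 50_000, 2_000, biotype="rRNA"),
            gene("ribo_pseudo", 70_000, 2_000, biotype="rRNA_pseudogene"),
            gene("ychrom", 10_000, 2_000, chrom="chrY"),
        ]
        kept, removed = filter_genes(genes, cfg)
        assert [g.gene_id for g in kept] == ["ok"]
        assert removed == {"short": 1, "biotype": 2, "chrom": 1}

    def test_multi_criterion_gene_attributed_to_first_rule(self):
        g = gene("bad", 10_000, 150, chrom="chrY", biotype="rRNA")
        _, removed = filter_genes([g], cfg)
        assert removed == {"short": 1, "biotype": 0, "chrom": 0}

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(2)
        genes = []
        for i in range(100):
            genes.append(
                gene(
                    f"g{i}",
                    tss=int(rng.integers(10_000, 1_000_000)),
                    length=int(rng.integers(100, 5_000)),
                    chrom=["chr1", "chrY"][rng.integers(2)],
                    biotype=["protein_coding", "rRNA", "lincRNA"][rng.integers(3)],
                )
            )
        kept, _ = filter_genes(genes, cfg)
        expected = [
            g.gene_id
            for g in genes
            if g.union_exon_length >= 200 and g.biotype != "rRNA" and g.chrom != "chrY"
        ]
        assert [g.gene_id for g in kept] == expected


class TestFpkm:
    def test_worked_example(self):
        # 100 fragments on a 1 kb gene in a 1 M-fragment library -> FPKM 100
        g = gene("g1", length=999)  # union exon length 1000
        filler = gene("g2", tss=100_000, length=9_999)  # 10 kb
        table = pd.DataFrame({"rep1": [100, 999_900]}, index=pd.Index(["g1", "g2"], name="gene_id"))
        rec = fpkm(table, [g, filler], cfg)[0]
        assert rec.fpkm_per_replicate[0] == pytest.approx(100.0)

    def test_invariant_under_count_scaling(self):
        genes = [gene(f"g{i}", tss=20_000 * (i + 1), length=999 + i) for i in range(5)]
        counts = pd.DataFrame(
            {"rep1": [10, 20, 30, 40, 50]}, index=pd.Index([g.gene_id for g in genes], name="gene_id")
        )
        a = fpkm(counts, genes, cfg)
        b = fpkm(counts * 7, genes, cfg)
        for ra, rb in zip(a, b):
            assert ra.fpkm_mean == pytest.approx(rb.fpkm_mean)

    def test_doubling_length_halves_fpkm(self):
        g1 = [gene("g", length=999), gene("f", tss=50_000, length=4_999)]
        g2 = [gene("g", length=1_999), gene("f", tss=50_000, length=4_999)]
        counts = pd.DataFrame({"rep1": [100, 900]}, index=pd.Index(["g", "f"], name="gene_id"))
        a = fpkm(counts, g1, cfg)[0].fpkm_per_replicate[0]
        b = fpkm(counts, g2, cfg)[0].fpkm_per_replicate[0]
        assert b == pytest.approx(a / 2)

    def test_mean_is_arithmetic_over_replicates(self):
        g = [gene("g", length=999)]
        counts = pd.DataFrame({"rep1": [100], "rep2": [300]}, index=pd.Index(["g"], name="gene_id"))
        rec = fpkm(counts, g, cfg)[0]
        assert rec.fpkm_mean == pytest.approx(np.mean(rec.fpkm_per_replicate))

    def test_matches_independent_two_line_oracle(self):
        rng = np.random.default_rng(55)
        genes = [gene(f"g{i}", tss=15_000 * (i + 1), length=int(rng.integers(500, 3_000))) for i in range(20)]
        counts = pd.DataFrame(
            {
                "rep1": rng.integers(0, 1_000, 20),
                "rep2": rng.integers(0, 1_000, 20),
            },
            index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        )
        recs = fpkm(counts, genes, cfg)
        lengths = np.array([g.union_exon_length for g in genes])
        oracle = counts.to_numpy() * 1e9 / (lengths[:, None] * counts.to_numpy().sum(0)[None, :])
        got = np.array([r.fpkm_per_replicate for r in recs])
        assert np.allclose(got, oracle)

    def test_unknown_gene_and_empty_library_rejected(self):
        g = [gene("g", length=999)]
        with pytest.raises(KeyError, match="mystery"):
            fpkm(pd.DataFrame({"rep1": [1]}, index=pd.Index(["mystery"])), g, cfg)
        with pytest.raises(ValueError, match="zero total"):
            fpkm(pd.DataFrame({"rep1": [0]}, index=pd.Index(["g"])), g, cfg)


def test_htseq_summary_rows_dropped(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text("gene_id\trep1\trep2\ng1\t5\t7\n__no_feature\t100\t90\n__ambiguous\t3\t2\n")
    table = read_counts_table(p)
    assert list(table.index) == ["g1"]


class TestBoundGenes:
    def test_peak_straddling_tss_binds(self):
        g = gene("g", tss=10_000)
        ps = PeakSet("f", [Peak(GenomicInterval("chr1", 9_900, 10_100))])
        assert bound_genes(ps, [g], cfg) == {"g"}

    def test_distal_peak_does_not_bind(self):
        g = gene("g", tss=10_000)
        ps = PeakSet("f", [Peak(GenomicInterval("chr1", 7_500, 8_000))])
        assert bound_genes(ps, [g], cfg) == set()

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(12)
        genes = [
            gene(f"g{i}", tss=int(rng.integers(6_000, 200_000)), strand="+-"[rng.integers(2)])
            for i in range(40)
        ]
        peaks = PeakSet(
            "f",
            [
                Peak(GenomicInterval("chr1", s, s + int(rng.integers(100, 600))))
                for s in rng.integers(0, 200_000, 80)
            ],
        )
        got = bound_genes(peaks, genes, cfg)
        expected = set()
        for g in genes:
            win = stranded_window(g, g.tss, cfg.promoter_window)
            if any(overlaps(win, p.interval) for p in peaks):
                expected.add(g.gene_id)
        assert got == expected


def _records(values_by_group):
    recs = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            r = ExpressionRecord(f"{group}{i}", (0,), 1_000, (float(v),), float(v))
            r.group = group
            recs.append(r)
    return recs


class TestCompareGroups:
    def test_identical_groups_give_null_statistic(self):
        recs = _records({"nonbound": [1, 2, 3], "dual": [1, 2, 3]})
        (c,) = compare_groups(recs, groups=("nonbound", "dual"))
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_small_group_rejected(self):
        recs = _records({"nonbound": [1, 2, 3], "dual": [1, 2]})
        with pytest.raises(ValueError, match="dual"):
            compare_groups(recs, groups=("nonbound", "dual"))

    def test_welch_df_and_p_match_scipy_on_log_scale(self):
        rng = np.random.default_rng(19)
        a, b = rng.gamma(2, 50, 30), rng.gamma(2, 120, 40)
        recs = _records({"nonbound": a, "dual": b})
        (c,) = compare_groups(recs, groups=("nonbound", "dual"))
        ref = stats.ttest_ind(np.log2(a + 1), np.log2(b + 1), equal_var=False)
        assert c.statistic == pytest.approx(ref.statistic)
        assert c.p_value == pytest.approx(ref.pvalue)
        assert c.n_a == 30 and c.n_b == 40

    def test_welch_p_agrees_with_permutation_oracle(self):
        """On small groups the Welch p is close to a permutation p."""
        rng = np.random.default_rng(101)
        a = rng.normal(4.0, 1.0, 12)
        b = rng.normal(5.0, 1.2, 15)
        recs = _records({"nonbound": 2.0**a - 1, "dual": 2.0**b - 1})
        (c,) = compare_groups(recs, groups=("nonbound", "dual"))

        def welch_t(x, y):
            return stats.ttest_ind(x, y, equal_var=False).statistic

        perm = stats.permutation_test(
            (a, b), welch_t, permutation_type="independent",
            alternative="two-sided", n_resamples=10_000,
            rng=np.random.default_rng(0),
        )
        assert c.p_value == pytest.approx(perm.pvalue, abs=0.02)


class TestGroupPartition:
    def test_groups_partition_the_filtered_universe(self, sim, final_peaks):
        filtered, _ = filter_genes(sim.annotation.genes, cfg)
        universe = [g.gene_id for g in filtered]
        table = sim.counts.loc[sim.counts.index.intersection(universe)]
        recs = fpkm(table, filtered, cfg)
        ba = bound_genes(final_peaks["A"][0], filtered, cfg)
        bb = bound_genes(final_peaks["B"][0], filtered, cfg)
        assign_groups(recs, ba, bb, universe)
        groups = {}
        for r in recs:
            groups.setdefault(r.group, set()).add(r.gene_id)
        assert set().union(*groups.values()) == set(universe)
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                assert not (groups[a] & groups[b])

    def test_groups_match_surviving_consensus_peaks(self, sim, final_peaks, cfg):
        """Labels equal the planted truth restricted to sites that survived
        the (lossy) replicate consensus — the pipeline itself is faithful."""
        filtered, _ = filter_genes(sim.annotation.genes, cfg)
        universe = [g.gene_id for g in filtered]
        table = sim.counts.loc[sim.counts.index.intersection(universe)]
        recs = fpkm(table, filtered, cfg)
        ba = bound_genes(final_peaks["A"][0], filtered, cfg)
        bb = bound_genes(final_peaks["B"][0], filtered, cfg)
        assign_groups(recs, ba, bb, universe)
        # reconstruct expectation from truth + which sites survived
        surv = {}
        for factor in ("A", "B"):
            final = final_peaks[factor][0]
            from peakscape.intervals import IntervalIndex

            idx = IntervalIndex(final.intervals())
            surv[factor] = {
                gid
                for gid, chrom, s in sim.truth.sites(factor)
                if idx.overlaps_any(chrom, s - 150, s + 150)
            }
        for r in recs:
            in_a, in_b = r.gene_id in surv["A"], r.gene_id in surv["B"]
            expected = (
                "dual" if in_a and in_b else "A_only" if in_a else "B_only" if in_b else "nonbound"
            )
            assert r.group == expected
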