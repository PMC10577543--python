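import numpy as np
import pytest
from hypothesis import given, strategies as st

from poolscan import poolio, simcohort as sc
from conftest import make_design, make_freq


class TestVcfRoundTrip:
    def test_written_counts_read_back_identically(self, small_scenario, tmp_path):
        s = small_scenario
        path = tmp_path / "pools.vcf"
        sc.write_vcf(s.counts, s.panel.variants, s.region, str(path))
        counts = poolio.read_pooled_vcf(str(path), s.design)
        assert counts.pool_ids == s.counts.pool_ids
        assert counts.variant_ids == s.counts.variant_ids
        assert np.array_equal(counts.depths, s.counts.depths)
        assert np.array_equal(counts.alt_counts, s.counts.alt_counts)

    def test_empty_vcf_body(self, tmp_path):
        design = make_design(1, 1, 2)
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr9,length=1000>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            "case0\tctrl0\n")
        counts = poolio.read_pooled_vcf(str(path), design)
        assert counts.n_variants == 0
        assert counts.n_pools == 2

    def test_direct_field_copy(self, tmp_path):
        design = make_design(1, 1, 2)
        path = tmp_path / "one.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr9,length=1000>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcase0\tctrl0\n"
            "chr9\t100\tv1\tA\tC\t.\tPASS\t.\tAD\t20,10\t30,0\n")
        counts = poolio.read_pooled_vcf(str(path), design)
        assert counts.alt_counts.tolist() == [[10], [0]]
        assert counts.depths.tolist() == [[30], [30]]

    def test_multiallelic_split(self, tmp_path):
        design = make_design(1, 1, 2)
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr9,length=1000>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcase0\tctrl0\n"
            "chr9\t100\tv1\tA\tC,G\t.\tPASS\t.\tAD\t20,10,5\t30,0,3\n")
        counts = poolio.read_pooled_vcf(str(path), design)
        assert counts.variant_ids == ["v1_1", "v1_2"]
        assert counts.alt_counts.tolist() == [[10, 5], [0, 3]]
        assert counts.depths.tolist() == [[30, 25], [30, 33]]

    def test_pool_mismatch_errors(self, small_scenario, tmp_path):
        s = small_scenario
        path = tmp_path / "pools.vcf"
        sc.write_vcf(s.counts, s.panel.variants, s.region, str(path))
        bad = make_design(2, 2, 25)  # pool ids don't match the VCF
        with pytest.raises(ValueError, match="absent"):
            poolio.read_pooled_vcf(str(path), bad)


class TestEstimateFrequencies:
    def test_simple_ratio_and_weighted_cohort_mean(self):
        design = make_design(1, 1, 25)
        counts = sc.PooledCounts(depths=[[30], [30]], alt_counts=[[15], [3]],
                                 pool_ids=design.pool_ids, variant_ids=["v"])
        freq = poolio.estimate_frequencies(counts, design)
        assert freq.freqs[0, 0] == pytest.approx(0.5)
        # equal pools: combined frequency is the plain mean
        assert freq.af[0] == pytest.approx((0.5 + 0.1) / 2)

    def test_missing_cells_flagged_and_variant_dropped(self):
        design = make_design(2, 3, 10)
        depths = np.full((5, 2), 20)
        depths[:2, 1] = 0  # 40% of pools missing for second variant
        alt = np.minimum(depths, 4)
        counts = sc.PooledCounts(depths=depths, alt_counts=alt,
                                 pool_ids=design.pool_ids,
                                 variant_ids=["keep", "drop"])
        freq = poolio.estimate_frequencies(counts, design)
        assert freq.variant_ids == ["keep"]
        assert freq.dropped == ["drop"]

    def test_error_deconvolution_flag(self):
        design = make_design(1, 1, 10)
        counts = sc.PooledCounts(depths=[[1000], [1000]],
                                 alt_counts=[[206], [206]],
                                 pool_ids=design.pool_ids, variant_ids=["v"])
        freq = poolio.estimate_frequencies(counts, design, error_rate=0.01)
        assert freq.freqs[0, 0] == pytest.approx((0.206 - 0.01) / 0.98)

    def test_estimator_unbiased_for_error_convolved_frequency(self):
        # 38 pools at depth 30, f=0.2, eps=0.01 -> E[f_hat] = 0.206
        rng = np.random.default_rng(42)
        design = make_design(18, 20, 25)
        estimates = []
        for rep in range(300):
            depths = np.maximum(rng.poisson(30.0, size=(38, 1)), 1)
            alt = rng.binomial(depths, 0.206)
            counts = sc.PooledCounts(depths=depths, alt_counts=alt,
                                     pool_ids=design.pool_ids,
                                     variant_ids=["v"])
            freq = poolio.estimate_frequencies(counts, design)
            estimates.append(freq.af[0])
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.206) < 3 * se

    def test_shape_mismatch_rejected(self):
        design = make_design(1, 1, 10)
        counts = sc.PooledCounts(depths=np.full((3, 1), 10),
                                 alt_counts=np.zeros((3, 1), dtype=int),
                                 pool_ids=["a", "b", "c"], variant_ids=["v"])
        with pytest.raises(ValueError):
            poolio.estimate_frequencies(counts, design)


class TestNovelty:
    def test_counting(self):
        variants = [sc.VariantRecord(f"v{i}", i, "A", "C", 0.1)
                    for i in range(25)]
        known = {f"v{i}" for i in range(10)}
        out = poolio.flag_novelty(variants, known)
        assert sum(v.known for v in out) == 10
        assert sum(not v.known for v in out) == 15

    def test_empty_list_all_novel(self):
        variants = [sc.VariantRecord("x", 1, "A", "C", 0.1)]
        assert not poolio.flag_novelty(variants, set())[0].known


class TestFunctionalClassification:
    @staticmethod
    def region_with_cds(codon="GTG", pad_codons=3):
        # one gene: 9-base 5'UTR, CDS of pad+1+pad codons, intron tail
        cds_seq = "ATG" * pad_codons + codon + "ATG" * pad_codons
        seq = "A" * 9 + cds_seq + "T" * 30 + "C" * 10
        features = (
            sc.GeneFeature("G", "UTR5", 0, 9),
            sc.GeneFeature("G", "CDS", 9, 9 + len(cds_seq), frame=0),
            sc.GeneFeature("G", "intron", 9 + len(cds_seq),
                           9 + len(cds_seq) + 30),
        )
        return sc.RegionSpec("chr9", 0, len(seq), features, seq)

    def test_codon_change_nonsynonymous(self):
        # GTG (Val) -> GGG (Gly) at the middle codon's second base
        region = self.region_with_cds("GTG")
        pos = 9 + 9 + 1
        v = sc.VariantRecord("v", pos, "T", "G", 0.01)
        out = poolio.classify_functional([v], region)[0]
        assert out.functional_class == "nonsynonymous"

    def test_third_position_synonymous(self):
        # GTG (Val) -> GTA (Val)
        region = self.region_with_cds("GTG")
        pos = 9 + 9 + 2
        v = sc.VariantRecord("v", pos, "G", "A", 0.01)
        out = poolio.classify_functional([v], region)[0]
        assert out.functional_class == "synonymous"

    def test_precedence_and_intergenic(self):
        region = self.region_with_cds()
        utr = sc.VariantRecord("u", 4, "A", "C", 0.1)
        intron = sc.VariantRecord("i", 9 + 21 + 5, "T", "C", 0.1)
        inter = sc.VariantRecord("x", region.end - 1, "T", "C", 0.1)
        out = poolio.classify_functional([utr, intron, inter], region)
        assert [v.functional_class for v in out] == \
            ["UTR", "intronic", "intergenic"]

    def test_cds_frame_violation_rejected(self):
        seq = "A" * 20
        features = (sc.GeneFeature("G", "CDS", 0, 10, frame=0),)
        region = sc.RegionSpec("chr9", 0, 20, features, seq)
        v = sc.VariantRecord("v", 5, "A", "C", 0.1)
        with pytest.raises(ValueError, match="divisible"):
            poolio.classify_functional([v], region)


class TestMafBins:
    @given(st.lists(st.floats(0, 0.5), min_size=1, max_size=50))
    def test_every_maf_in_exactly_one_bin(self, mafs):
        idx = poolio.maf_bin_index(np.array(mafs))
        assert ((idx >= 0) & (idx < 6)).all()

    def test_edges(self):
        idx = poolio.maf_bin_index(np.array([0.0, 0.005, 0.01, 0.05,
                                             0.10, 0.25, 0.5]))
        assert idx.tolist() == [0, 1, 2, 3, 4, 5, 5]


class TestSummaryTable:
    def test_reference_grid_totals(self):
        t = poolio.SummaryTable.from_counts(poolio.REFERENCE_BIN_COUNTS)
        assert t.total == 2216
        assert t.class_total("SNP") == 2056
        assert t.class_total("complex") == 160
        assert t.novelty_total("novel") == 785
        assert t.novel_rare == 743
        assert t.pct_novel() == 35.4

    def test_reference_percentages(self):
        ref = poolio.REFERENCE_FUNCTIONAL_COUNTS
        assert poolio.percentage(ref["intronic"], ref["annotated_total"]) == 55.8
        assert poolio.percentage(ref["intergenic"], ref["annotated_total"]) == 40.7
        assert round(100 * ref["novel_singletons"] / 785) == 78

    def test_singleton_binning(self):
        design = make_design(18, 20, 25)
        freqs = np.full((38, 1), 1.0 / 1900.0)
        freq = make_freq(freqs, design)
        assert freq.mac[0] == 1
        variants = [sc.VariantRecord("v0", 1, "A", "C", 1.0 / 1900.0)]
        t = poolio.summarize_variants(variants, freq)
        assert t.n_singletons == 1
        assert t.bin_counts.loc["0%-0.5%", ("SNP", "novel")] == 1
        assert t.total == 1

    def test_percentages_recompute_from_cells(self):
        t = poolio.SummaryTable.from_counts(poolio.REFERENCE_BIN_COUNTS)
        d = t.to_json_dict()
        cells = sum(sum(b.values()) for b in d["bins"].values())
        assert cells == d["total"]
        assert d["pct_novel"] == round(100 * d["novel_total"] / d["total"], 1)

    def test_scenario_summary_consistency(self, small_scenario, small_freq):
        s = small_scenario
        variants = poolio.flag_novelty(s.panel.variants, set(s.known_ids))
        variants = poolio.classify_functional(variants, s.region)
        t = poolio.summarize_variants(variants, small_freq)
        assert t.total == small_freq.n_variants
        assert t.novelty_total("known") + t.novelty_total("novel") == t.total
        assert t.bin_counts.to_numpy().sum() == t.total


class TestConcordance:
    def test_identical_and_affine(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert poolio.concordance(x, x) == pytest.approx(1.0)
        assert poolio.concordance(x, 2 * x + 0.05) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            poolio.concordance(np.array([0.1, 0.1, 0.1]),
                               np.array([0.1, 0.2, 0.3]))

    def test_array_truth_vs_pooled_estimate(self):
        # 32 common variants, 38 pools; truth = realised cohort frequency
        rng = np.random.default_rng(0)
        design = make_design(18, 20, 25)
        hits = 0
        for seed in range(100):
            afs = rng.uniform(0.05, 0.5, 32)
            geno = rng.binomial(2, afs, size=(950, 32)).astype(np.int8)
            variants = [sc.VariantRecord(f"v{j}", j, "A", "C", afs[j])
                        for j in range(32)]
            labels = np.r_[np.ones(450, dtype=np.int8),
                           np.zeros(500, dtype=np.int8)]
            cohort = sc.Cohort(genotypes=geno, labels=labels,
                               variants=variants)
            counts = sc.simulate_pooled_reads(cohort, design, mean_depth=100,
                                              error_rate=0.001, seed=seed)
            freq = poolio.estimate_frequencies(counts, design)
            truth = cohort.allele_frequencies()
            hits += poolio.concordance(truth, freq.af) >= 0.99
        assert hits >= 95
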