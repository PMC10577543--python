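import numpy as np
import pytest

from poolscan import simcohort as sc


def tiny_region():
    return sc.RegionSpec("chr9", 0, 100_000)


class TestSimulateHaplotypes:
    def test_perfect_ld_forces_identical_columns(self):
        ld = sc.LDSpec(n_blocks=1, within_block_r2=1.0)
        panel = sc.simulate_haplotypes(tiny_region(), ld, n_hap=400,
                                       n_variants=3,
                                       af_spectrum=sc.constant_af_spectrum(0.3),
                                       seed=5)
        a = panel.alleles
        assert np.array_equal(a[:, 0], a[:, 1])
        assert np.array_equal(a[:, 0], a[:, 2])

    def test_cross_block_independence(self):
        ld = sc.LDSpec(n_blocks=2, within_block_r2=0.8)
        panel = sc.simulate_haplotypes(
            tiny_region(), ld, n_hap=4000, n_variants=10,
            af_spectrum=sc.uniform_af_spectrum(0.28, 0.32), seed=7)
        r = np.corrcoef(panel.alleles.T)
        blocks = np.array([v.block for v in panel.variants])
        cross = r[np.ix_(blocks == 0, blocks == 1)] ** 2
        assert cross.mean() < 0.05

    def test_within_block_r2_matches_target_over_seeds(self):
        # oracle: direct r^2 on the emitted matrix, target 0.8 +/- 0.1
        ld = sc.LDSpec(n_blocks=2, within_block_r2=0.8)
        means = []
        for seed in range(20):
            panel = sc.simulate_haplotypes(
                tiny_region(), ld, n_hap=2000, n_variants=12,
                af_spectrum=sc.uniform_af_spectrum(0.29, 0.31), seed=seed)
            r2 = np.corrcoef(panel.alleles.T) ** 2
            blocks = np.array([v.block for v in panel.variants])
            vals = []
            for b in (0, 1):
                idx = np.flatnonzero(blocks == b)
                sub = r2[np.ix_(idx, idx)]
                vals.append(sub[np.triu_indices_from(sub, 1)].mean())
            means.append(np.mean(vals))
        assert 0.7 <= np.mean(means) <= 0.9

    def test_unattainable_r2_raises(self):
        # rare and common variants cannot be strongly correlated
        ld = sc.LDSpec(n_blocks=1, within_block_r2=0.9)
        with pytest.raises(sc.LDUnattainableError):
            sc.simulate_haplotypes(
                tiny_region(), ld, n_hap=500, n_variants=6,
                af_spectrum=sc.uniform_af_spectrum(0.005, 0.5), seed=0)

    def test_too_few_variants_for_blocks(self):
        ld = sc.LDSpec(n_blocks=5, within_block_r2=0.3)
        with pytest.raises(ValueError):
            sc.simulate_haplotypes(tiny_region(), ld, n_hap=100,
                                   n_variants=3, seed=0)

    def test_realized_af_recorded(self):
        ld = sc.LDSpec(n_blocks=1, within_block_r2=0.2)
        panel = sc.simulate_haplotypes(
            tiny_region(), ld, n_hap=600, n_variants=5,
            af_spectrum=sc.uniform_af_spectrum(0.2, 0.4), seed=3)
        np.testing.assert_allclose(panel.frequencies(),
                                   [v.true_af for v in panel.variants])

    def test_seed_determinism(self):
        ld = sc.LDSpec(n_blocks=2, within_block_r2=0.3)
        kw = dict(n_hap=200, n_variants=8,
                  af_spectrum=sc.uniform_af_spectrum(0.25, 0.35))
        a = sc.simulate_haplotypes(tiny_region(), ld, seed=9, **kw)
        b = sc.simulate_haplotypes(tiny_region(), ld, seed=9, **kw)
        assert np.array_equal(a.alleles, b.alleles)
        assert [v.id for v in a.variants] == [v.id for v in b.variants]


class TestLinkedGroup:
    @staticmethod
    def base_panel(seed=4):
        ld = sc.LDSpec(n_blocks=1, within_block_r2=0.3)
        return sc.simulate_haplotypes(
            tiny_region(), ld, n_hap=2000, n_variants=4,
            af_spectrum=sc.uniform_af_spectrum(0.3, 0.4), seed=seed)

    def test_zero_linked_variants_is_identity(self):
        panel = self.base_panel()
        out = sc.attach_linked_haplotype_group(panel, 0.03, 0,
                                               panel.variants[0].id)
        assert np.array_equal(out.alleles, panel.alleles)
        assert [v.id for v in out.variants] == [v.id for v in panel.variants]

    def test_linked_variants_in_high_mutual_ld(self):
        panel = self.base_panel()
        out = sc.attach_linked_haplotype_group(panel, 0.03, 10,
                                               panel.variants[0].id,
                                               anchor_allele="alt", seed=2,
                                               tag="grp")
        cols = [i for i, v in enumerate(out.variants)
                if v.haplotype_tag == "grp"]
        assert len(cols) == 10
        r2 = np.corrcoef(out.alleles[:, cols].T) ** 2
        assert (r2[np.triu_indices(10, 1)] >= 0.9).all()
        # alternate allele appears only on anchor-allele carriers
        j = out.index_of(panel.variants[0].id)
        carriers = out.alleles[:, j] == 1
        for c in cols:
            assert np.all(out.alleles[~carriers, c] == 0)

    def test_carrier_freq_exceeding_anchor_rejected(self):
        ld = sc.LDSpec(n_blocks=1, within_block_r2=0.2)
        panel = sc.simulate_haplotypes(
            tiny_region(), ld, n_hap=1000, n_variants=3,
            af_spectrum=sc.constant_af_spectrum(0.03), seed=21)
        anchor = panel.variants[0]
        assert anchor.true_af < 0.045
        with pytest.raises(ValueError, match="exceeds"):
            sc.attach_linked_haplotype_group(panel, 0.045, 3, anchor.id,
                                             anchor_allele="alt")

    def test_carrier_equal_anchor_gives_perfect_ld(self):
        ld = sc.LDSpec(n_blocks=1, within_block_r2=0.2)
        panel = sc.simulate_haplotypes(
            tiny_region(), ld, n_hap=1000, n_variants=3,
            af_spectrum=sc.constant_af_spectrum(0.04), seed=8)
        anchor = panel.variants[0]
        out = sc.attach_linked_haplotype_group(
            panel, anchor.true_af, 2, anchor.id, "alt", seed=1, tag="g")
        j = out.index_of(anchor.id)
        for c in [i for i, v in enumerate(out.variants)
                  if v.haplotype_tag == "g"]:
            assert np.array_equal(out.alleles[:, c], out.alleles[:, j])


class TestPhenotypes:
    def test_null_model_equal_frequencies(self):
        panel = TestLinkedGroup.base_panel(seed=12)
        model = sc.RiskModel(flag_effects={panel.variants[0].id: 0.0})
        diffs = []
        for s in range(30):
            cohort = sc.assign_phenotypes(panel, model, 200, 200, seed=s)
            f = cohort.allele_frequencies(cohort.labels == 1)[0] - \
                cohort.allele_frequencies(cohort.labels == 0)[0]
            diffs.append(f)
        se = np.sqrt(2 * 0.35 * 0.65 / 400) / np.sqrt(30)
        assert abs(np.mean(diffs)) < 4 * se

    def test_extreme_effect_removes_risk_allele_from_cases(self):
        panel = TestLinkedGroup.base_panel(seed=13)
        vid = panel.variants[0].id
        model = sc.RiskModel(flag_effects={vid: -20.0})
        cohort = sc.assign_phenotypes(panel, model, 150, 150, seed=1)
        f_case = cohort.allele_frequencies(cohort.labels == 1)[0]
        assert f_case < 0.01

    def test_frequency_difference_matches_analytic_oracle(self):
        # oracle: numerical integration over genotype classes
        af, beta = 0.5, -0.25
        expect = sc.expected_frequency_difference(beta, af)
        ld = sc.LDSpec(n_blocks=1, within_block_r2=0.0)
        diffs = []
        for s in range(200):
            panel = sc.simulate_haplotypes(
                sc.RegionSpec("c", 0, 1000), ld, n_hap=2000, n_variants=1,
                af_spectrum=sc.constant_af_spectrum(af), seed=s)
            vid = panel.variants[0].id
            model = sc.RiskModel(flag_effects={vid: beta})
            cohort = sc.assign_phenotypes(panel, model, 450, 500, seed=s)
            diffs.append(
                cohort.allele_frequencies(cohort.labels == 1)[0]
                - cohort.allele_frequencies(cohort.labels == 0)[0])
        se = np.sqrt(0.25 / 900 + 0.25 / 1000) / np.sqrt(200)
        # allow for the spread of realized panel frequencies around 0.5
        assert abs(np.mean(diffs) - expect) < 4 * se + 0.002

    def test_unattainable_quota_raises(self):
        panel = TestLinkedGroup.base_panel(seed=14)
        model = sc.RiskModel(baseline_logit=-40.0)
        with pytest.raises(RuntimeError):
            sc.assign_phenotypes(panel, model, 100, 100, seed=0,
                                 max_draw_factor=5)


class TestPooledReads:
    @staticmethod
    def fixed_fraction_cohort(f, n_pools, pool_size=25):
        """Every pool has exactly f * 2 * pool_size alternate chromosomes."""
        n_ind = n_pools * pool_size
        geno = np.zeros((n_ind, 1), dtype=np.int8)
        per_pool_alt = int(round(f * 2 * pool_size))
        for k in range(n_pools):
            start = k * pool_size
            full, rem = divmod(per_pool_alt, 2)
            geno[start:start + full, 0] = 2
            if rem:
                geno[start + full, 0] = 1
        variants = [sc.VariantRecord("v0", 0, "A", "C", f)]
        labels = np.r_[np.ones(n_ind // 2, dtype=np.int8),
                       np.zeros(n_ind - n_ind // 2, dtype=np.int8)]
        cohort = sc.Cohort(genotypes=geno, labels=labels, variants=variants)
        pools = tuple(
            sc.Pool(f"p{k}", "case" if k < n_pools // 2 else "control",
                    tuple(range(k * pool_size, (k + 1) * pool_size)))
            for k in range(n_pools))
        return cohort, sc.PoolDesign(pools=pools, pool_size=pool_size)

    def test_zero_fraction_zero_error_gives_zero_alt(self):
        cohort, design = self.fixed_fraction_cohort(0.0, 10)
        counts = sc.simulate_pooled_reads(cohort, design, 30, 0.0, seed=0)
        assert counts.alt_counts.sum() == 0

    def test_error_convolved_mean_alt_fraction(self):
        # closed form: E[alt/depth] = f(1-e) + (1-f)e = 0.206
        cohort, design = self.fixed_fraction_cohort(0.2, 2000)
        counts = sc.simulate_pooled_reads(cohort, design, 30, 0.01, seed=3)
        frac = counts.alt_counts / counts.depths
        mc_se = frac.std() / np.sqrt(frac.size)
        assert abs(frac.mean() - 0.206) < 3 * mc_se

    def test_high_depth_recovers_fraction(self):
        cohort, design = self.fixed_fraction_cohort(0.3, 10)
        counts = sc.simulate_pooled_reads(cohort, design, 20000, 0.0, seed=1)
        np.testing.assert_allclose(counts.alt_counts / counts.depths, 0.3,
                                   atol=0.02)

    def test_true_fraction_conservation(self, small_scenario):
        # pool-size-weighted true fractions reproduce cohort frequencies
        s = small_scenario
        sizes = s.design.pool_sizes()
        agg = (s.counts.true_fractions * sizes[:, None]).sum(0) / sizes.sum()
        np.testing.assert_allclose(agg, s.cohort.allele_frequencies(),
                                   atol=1e-12)

    def test_depths_positive_and_seeded(self, small_scenario):
        s = small_scenario
        assert (s.counts.depths >= 1).all()
        again = sc.simulate_pooled_reads(
            s.cohort, s.design, s.counts.mean_depth, s.counts.error_rate,
            seed=0)
        twice = sc.simulate_pooled_reads(
            s.cohort, s.design, s.counts.mean_depth, s.counts.error_rate,
            seed=0)
        assert np.array_equal(again.alt_counts, twice.alt_counts)


class TestScenario:
    def test_geometry_and_uniqueness(self, small_scenario):
        s = small_scenario
        assert s.design.n_pools == 38
        assert sum(p.cohort == "case" for p in s.design.pools) == 18
        ids = [i for p in s.design.pools for i in p.individual_ids]
        assert len(ids) == len(set(ids)) == 950

    def test_flags_planted_with_risk_alleles(self, small_scenario):
        flags = {v.id: v for v in small_scenario.panel.variants
                 if v.risk_allele is not None}
        assert set(flags) == {f.id for f in small_scenario.flags}
        assert len(flags) == 5

    def test_linked_groups_low_frequency(self, small_scenario):
        s = small_scenario
        case = s.cohort.labels == 1
        f_case = s.cohort.allele_frequencies(case)
        f_ctrl = s.cohort.allele_frequencies(~case)
        f_all = s.cohort.allele_frequencies()
        for tag, enriched_in_cases in (("risk_hap", False),
                                       ("protective_hap", True)):
            cols = [i for i, v in enumerate(s.panel.variants)
                    if v.haplotype_tag == tag]
            assert cols
            maf = np.minimum(f_all[cols], 1 - f_all[cols])
            assert (maf < 0.06).all()
            d = (f_case[cols] - f_ctrl[cols]).mean()
            assert (d > 0) == enriched_in_cases
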