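# Methods

`poolscan` analyses deep pooled resequencing of a single disease-associated
locus in a case–control design: DNA from equal-size groups of individuals
is sequenced as one library per pool, so the data are per-pool allele
*fractions*, never individual genotypes. Every statistical choice below
follows from that constraint. The package was built around the canonical
use case of a 230 kb GWAS interval at 9p21.3 (chr9:21,950,000–22,180,000,
hg19) sequenced in 450 long-lived cases (18 pools) and 500 controls (20
pools) of 25 individuals each, but nothing in the code is specific to that
locus.

## Frequency estimation (poolio)

The per-pool alternate-allele frequency is the ratio alt/depth of
allele-supporting read counts from the VCF `AD` field. Cohort frequencies
are pool averages weighted by chromosome count (2 × pool size). Cells with
zero depth are missing; a variant is dropped when more than 20% of pools
are missing (configurable — the underlying studies publish no QC rule, so
a conservative default is used). Minor-allele counts (MAC) are rounded
dosages on the combined cohorts (`round(maf · 2N)`); "singleton" means
MAC = 1. MAF summary bins are half-open — [0, 0.5%), [0.5, 1%), [1, 5%),
[5, 10%), [10, 25%) — with the last bin closed at 50%; functional
annotation is restricted to variants with MAC ≥ 4.

No sequencing-error correction is applied by default: with the error rate
ε unknown in real data, the raw estimator is unbiased for the
error-convolved frequency f′ = f(1−ε) + (1−f)ε, not for f. An optional
de-convolution f̂ = (p̂−ε)/(1−2ε) is available when ε is known.

Functional consequence uses a plus-strand gene model with per-feature
precedence CDS > UTR > noncoding exon > intron > intergenic; CDS variants
are translated through the spliced coding sequence with the standard
codon table (synonymous vs nonsynonymous). A CDS whose spliced length is
not a multiple of 3 is rejected at load.

## Single-variant association (assoc)

Allele-count 2×2 tables are reconstructed from rounded per-cohort dosages.
The primary p-value is the two-sided chi-square test without continuity
correction, switching to the exact conditional (hypergeometric) test when
any expected cell is below 5; odds ratios use the Haldane–Anscombe 0.5
correction when a cell is zero, with Woolf log-OR normal-approximation
confidence intervals. Multiplicity is handled by Bonferroni.

**Caveat that drives the module design:** allele-count tests treat the
reconstructed counts as a multinomial sample of 2N chromosomes, but
pooled sequencing adds read-sampling variance on top of chromosome
sampling. At low depth this inflates the chi-square statistic badly (we
measure per-test type-I error ≈ 0.22 at 30 reads per pool). The tests are
therefore calibrated only in the deep-sequencing regime, and a companion
pool-aware p-value (two-sided Mann–Whitney rank test on per-pool
frequencies between cohorts) is always emitted alongside; it is valid at
any depth because pools are its sampling units.

The forest table reports per-trait odds ratios for flagged GWAS variants,
re-oriented to the designated risk allele so OR < 1 means risk-allele
depletion in cases.

## LD structure and tag selection (ldtags)

True haplotypic r² is unobservable in pooled data; the Pearson correlation
of per-pool frequencies serves as a composite-LD proxy, and is labelled as
such. Blocks are recovered by average-linkage hierarchical clustering on
the distance 1 − r²; tag variants are selected greedily in priority order
(association significance, ties by position) under a pairwise r² ceiling
of 0.1, each tag representing the candidates correlated with it above the
ceiling. The pairwise ceiling is asserted on every output.

With 38 pools the sample-correlation noise floor is E[r²] ≈ 1/37 ≈ 0.027,
so even variants that are independent in the population occasionally show
pool-level r² > 0.1; a tag set of 5 candidates in 5 distinct blocks
therefore sometimes loses one candidate to chance correlation. This is a
property of pool-estimated LD, not of the algorithm.

## Combined risk-allele depletion test (riskperm)

The headline statistic is the standardized sum over tag variants of
risk-allele frequency differences,

T = Σ_t (f̄_risk,control − f̄_risk,case) / SE_t,

with SE_t the two-sample standard error computed from per-pool
frequencies. Positive T means combined depletion in cases. The null is
generated by permuting pool cohort labels, preserving the 18/20 pool
split — pools, not individuals, are the exchangeable units in pooled data
— and the empirical p uses the add-one rule, so p ≥ 1/(n_perm+1). The
default 10,000 permutations give a minimum attainable p of 10⁻⁴, the
resolution of the bound typically quoted for such tests. One-sided
(depletion) is the default because the hypothesis is directional. Small
designs can be enumerated exhaustively, in which case the p-value is the
exact fraction of labelings at least as extreme (including the observed
one). Fisher's combined-p and sum-of-log-OR variants are available as
alternative statistics through the generic permutation driver.

## Pool-profile PCA and the two-profile pattern (multivar)

PCA runs on the centered, unscaled pools × variants frequency matrix
restricted to MAC ≥ 4 (scaling would up-weight rare-variant read noise);
component signs are fixed deterministically (largest-|loading| entry
positive) for reproducibility. Per-component cohort separation uses the
two-sided Mann–Whitney test, exact for ≤ 25 pools per cohort without
ties. `screen_components` applies a Bonferroni correction across the
screened components. Pool classification from selected components is a
linear SVM (C = 1; with ~38 points in 2 dimensions the margin penalty is
not sensitive) with leave-one-pool-out accuracy and a label-permutation
p-value, the classifier refit for every permutation. Feature importance
comes from |loadings| (top 20 per component by default) and from
tree-ensemble permutation importance averaged over refits.

`find_separating_components` operationalises the published two-profile
pattern — a risk-linked and a protective-linked group of low-frequency
variants appearing as separate leading components. Each of the top five
components is oriented along its aggregate low-frequency minor-allele
direction (a linked group of n variants contributes loading mass ~ √n,
so the dominant group sets the sign) and summarised by the mean
correlation, across pools, of its oriented score with the flag variants'
risk-allele frequencies. The most positive and most negative components
(each beyond ±0.1, roughly one null standard deviation of the statistic)
are the candidate risk and protective profiles; the pattern is declared
found when the pair jointly separates cohorts by the permutation-validated
classifier at α = 0.05. Two deliberate choices:

* selection is label-blind (correlations are computed across pools without
  reference to cohort labels), so the classifier permutation p is an
  unbiased gate;
* per-component rank-test p-values are reported but are not gates. All
  label-linked mean structure lies on a single direction in pool space, so
  when one profile's component captures most of that direction the other
  component's own rank test is mechanically diluted even though the pair
  separates the cohorts clearly; demanding two individually significant
  rank tests would reject exactly the configuration the joint classifier
  detects. This mirrors how such patterns are evidenced in practice: one
  component nominally significant, the second suggestive, the pair
  validated jointly.

## Kernel and burden tests (kerneltest)

Individual genotypes do not exist, so pools are the test units with
expected dosages G[p,v] = 2 · pool_size · f̂[p,v] (pseudo-individual
expansion was rejected: it fabricates unobserved genotypes and overstates
the effective sample size). The variance-component score statistic is
Q = (y−μ̂)ᵀ G W² Gᵀ (y−μ̂) with Beta(1,25)-density MAF weights (the
conventional up-weighting of rarer variants) and an intercept-only
logistic null (μ̂ = case-pool fraction) unless covariates are supplied.
The null distribution of Q is the eigenvalue-weighted mixture of χ²₁
variables from the null-projected kernel (eigenvalues below 10⁻⁸ of the
largest are dropped); tail probabilities come from moment matching (mean,
variance and kurtosis matched to a scaled noncentral chi-square), which is
exact when all eigenvalues are equal, with a Monte-Carlo quadratic-form
sampler as fallback and cross-check. The directional burden test collapses
weighted minor-allele dosages per pool and compares cohorts by a
standardized difference under pool-label permutation; its sign reports
depletion (negative) versus enrichment of minor alleles in case pools.
Region scans report raw p-values, one row per region × test, with explicit
no-test rows for regions emptied by the MAC filter.

## Synthetic cohorts (simcohort)

The generator reproduces the statistical structure the analysis assumes,
layer by layer:

* **Haplotypes.** Each LD block has a latent biallelic anchor; a variant
  with frequency p is a noisy copy of the anchor with correlation
  t^(1/4), so two block-mates (conditionally independent given the
  anchor) have pairwise r² ≈ t. Binary correlation is bounded by the
  frequency ratio, so an unattainable target raises an error by default
  (`clamp` rides the background at maximal attainable correlation, the
  natural model for rare variants on a common background: high D′, low
  r²). Realized column frequencies are recorded as ground truth.
* **Spectrum.** The default allele-frequency spectrum draws MAF bins with
  the occupancy proportions observed in deep targeted sequencing of such
  a locus (dominated by rare variants, with a secondary common mass) and
  uniformly within bins.
* **Linked groups.** A low-frequency group is a set of variants sharing
  one carrier sub-haplotype. The carrier background can be a single
  anchor allele or a combination — the default study places the
  risk-linked group on haplotypes carrying the risk allele at ≥ 4 of the
  5 flags and the protective group on ≥ 4 non-risk alleles, the
  "combined-risk haplotype" structure that makes group frequencies track
  every flag's risk allele. Group tags never overwrite one another
  (distinct ancestral backgrounds).
* **Phenotypes.** Individuals are haplotype pairs drawn with replacement
  (Hardy–Weinberg, no family structure); the longevity label is Bernoulli
  with logit = baseline + Σ β·dosage over flag variants plus per-copy
  haplotype-tag effects. Sampling continues until both cohort quotas are
  filled; an analytic genotype-class integration
  (`expected_frequency_difference`) serves as the oracle for the realized
  case–control frequency difference.
* **Pools and reads.** Individuals are partitioned into equal pools by a
  seedable permutation (pool construction is unstated in such studies and
  treated as arbitrary). Depth per pool-variant is Poisson, clamped at
  ≥ 1 (variant sites are covered by construction); alternate reads are
  Binomial(depth, f′) with f′ = f(1−ε) + (1−f)ε and ε a flat per-read
  substitution error (default 10⁻³).

**Depth.** "30× average depth" for a pooled library is interpreted
per individual genome: a 25-individual pool sequenced at 30× per genome
sees ~750 reads per site, and the default `mean_depth` is 750. At 30
reads per pool the frequency matrix is essentially pure read noise — no
LD blocks, no component structure, and singletons (pool fraction 1/50)
would be undetectable — which is incompatible with what such studies
report. Operations that model sparse designs still accept any depth, and
the depletion-test calibration and power checks are run at 30 reads per
pool as the stress case.

**Calibrated defaults.** The two linked groups default to 150 variants at
carrier frequency 0.045 with log-odds −0.9 (risk-linked, depleted in
cases) and 50 variants at carrier frequency 0.03 with log-odds +2.2
(protective, enriched in cases); flags carry −0.25 per risk allele
(OR ≈ 0.78). Group sizes, carrier frequencies and effects were calibrated
once, against the qualitative phenomenon the generator exists to emulate —
low-frequency (combined MAF < 5%) groups appearing as separate leading
components with opposite risk-allele correlations — and then frozen.
The asymmetry between the groups is essential: two profiles of equal
strength merge into a single contrast component (all label-linked mean
structure shares one pool-space axis), which is why the generator makes
one group large/weak and the other small/strong.

**What the generator does not model:** coalescent or recombination-map
realism, sequencing-quality variation beyond a flat substitution error,
indel realignment artifacts, batch effects, or family structure. Passing
tests therefore demonstrate that the pipeline's statistics behave
correctly under the idealised pooled-sampling model, not that the
pipeline is robust to real-data artifacts.

## Problem sizes used in the test suite

Unit tests run on reduced panels (hundreds of haplotypes/variants).
The statistical acceptance checks use: 500 null and 200 alternative
cohorts (five tags, full 950-individual cohorts, 30 reads per pool,
999 permutations) for depletion-test calibration and power; 100 seeds of
the full default study (~2,200 variants, 750× pools) for the two-profile
pattern; 100 null seeds of an 800-variant label-independent panel for the
component null control; and a 10⁶-draw Monte-Carlo oracle for the kernel
p-value engine. `scripts/acceptance.py` recomputes the same quantities at
moderately reduced replicate counts (200/100 calibration runs, 30 pattern
seeds) so a complete run stays in the minutes range on one CPU.

## Known limitations

* Allele-count association tests are anti-conservative at low depth (use
  the pool-aware p-value there).
* Pool-estimated r² has a 1/(n_pools−1) noise floor; tag selection at a
  0.1 ceiling near that floor is noisy.
* The exact Mann–Whitney branch requires tie-free scores; ties fall back
  to the corrected normal approximation.
* Moment-matching kernel p-values are accurate in the moderate tail
  (relative error ≲ 15% for p ≥ 0.01) but are not a substitute for the
  Monte-Carlo sampler in the far tail.
* The two-profile pattern search assumes the flag risk alleles are known;
  with misspecified risk alleles the orientation of the pattern flips.
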