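"""Synthetic pooled case-control cohorts for a regional sequencing study.

This module generates every layer of data the downstream pipeline consumes:

1. a binary haplotype panel over a genomic region, organised into LD blocks;
2. optional low-frequency variant groups riding on a carrier haplotype
   (the "linked haplotype group" pattern seen as distinct principal
   components in pooled genotype profiles);
3. diploid individuals with a longevity phenotype drawn from a logistic
   (liability) risk model over flagged GWAS variants and haplotype tags;
4. a pooled sequencing design (pools of equal size per cohort) and
   per-pool read counts at every variant.

The LD engine is deliberately simple and auditable: each block carries a
latent biallelic "anchor" background, and every variant in the block is a
noisy copy of that background.  A variant is emitted with correlation
t^(1/4) to the anchor, where t is the requested within-block r-squared;
two block-mates are conditionally independent given the anchor, so their
correlation is the product of their anchor correlations and their pairwise
r-squared is close to t.  Correlation between two binary variables with
unequal frequencies is bounded; when t^(1/4) exceeds the bound the
behaviour is controlled by ``on_unattainable`` ("error" by default,
"clamp" to ride the background at the maximal attainable correlation).

All operations take an explicit integer seed; there is no global random
state.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "GeneFeature",
    "RegionSpec",
    "LDSpec",
    "VariantRecord",
    "HaplotypePanel",
    "RiskModel",
    "Pool",
    "PoolDesign",
    "PooledCounts",
    "Cohort",
    "FlagSNP",
    "LDUnattainableError",
    "af_spectrum_from_bins",
    "default_region",
    "default_scenario",
    "simulate_haplotypes",
    "attach_linked_haplotype_group",
    "assign_phenotypes",
    "build_pool_design",
    "simulate_pooled_reads",
    "expected_frequency_difference",
    "write_vcf",
    "write_pool_design",
    "write_ground_truth",
    "write_flag_snps",
    "write_known_ids",
    "write_regions_bed",
]

FEATURE_CLASSES = ("CDS", "UTR5", "UTR3", "intron", "noncoding_exon")
FUNCTIONAL_CLASSES = (
    "intergenic",
    "intronic",
    "UTR",
    "synonymous",
    "nonsynonymous",
    "noncoding_exonic",
)


class LDUnattainableError(ValueError):
    """Requested within-block r-squared cannot be realised for the drawn
    allele frequencies (binary correlation is bounded by the frequency
    ratio)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """One annotated interval of a gene model (0-based, half-open).

    ``frame`` is required for CDS features: the index (0/1/2) of the codon
    position at which the feature starts, on the plus strand.
    """

    gene: str
    feature_class: str
    start: int
    end: int
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.start >= self.end:
            raise ValueError("feature start must precede end")
        if self.feature_class == "CDS" and self.frame not in (0, 1, 2):
            raise ValueError("CDS features require frame in {0,1,2}")


@dataclass(frozen=True)
class RegionSpec:
    """A genomic region with a stylised gene model and reference sequence."""

    chrom: str
    start: int
    end: int
    gene_features: tuple[GeneFeature, ...] = ()
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must precede end")
        for f in self.gene_features:
            if f.start < self.start or f.end > self.end:
                raise ValueError(f"feature {f.gene}/{f.feature_class} outside region")
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length must equal region length")

    @property
    def length(self) -> int:
        return self.end - self.start

    def base_at(self, position: int) -> str:
        if self.sequence is None:
            raise ValueError("region has no reference sequence")
        return self.sequence[position - self.start]


@dataclass(frozen=True)
class LDSpec:
    """Target linkage-disequilibrium structure: independent blocks with a
    common within-block pairwise r-squared target."""

    n_blocks: int
    within_block_r2: float
    between_block_r2: float = 0.0
    block_boundaries: tuple[int, ...] | None = None  # internal boundaries, sorted

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must be in [0, 1]")
        if not 0.0 <= self.between_block_r2 <= 0.05:
            raise ValueError("only (near-)independent blocks are supported; "
                             "between_block_r2 must be <= 0.05")
        if self.block_boundaries is not None:
            b = self.block_boundaries
            if len(b) != self.n_blocks - 1 or list(b) != sorted(b):
                raise ValueError("need n_blocks-1 sorted internal boundaries")


@dataclass
class VariantRecord:
    """A biallelic variant with simulation ground truth and annotation."""

    id: str
    position: int
    ref: str
    alt: str
    true_af: float
    vclass: str = "SNP"  # "SNP" or "complex"
    known: bool = False
    functional_class: str | None = None
    risk_allele: str | None = None  # "ref" or "alt" for flag variants
    trait: str | None = None
    beta: float = 0.0
    block: int | None = None
    haplotype_tag: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        is_snp = len(self.ref) == 1 and len(self.alt) == 1
        if self.vclass == "SNP" and not is_snp:
            raise ValueError("SNP requires single-base alleles")
        if self.risk_allele not in (None, "ref", "alt"):
            raise ValueError("risk_allele must be 'ref', 'alt' or None")


@dataclass
class HaplotypePanel:
    """Binary haplotype-by-variant matrix (0 = reference, 1 = alternate)."""

    alleles: np.ndarray  # (n_hap, n_variants) uint8
    variants: list[VariantRecord]
    haplotype_tags: list[str | None] | None = None
    region: RegionSpec | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.variants):
            raise ValueError("alleles shape inconsistent with variant list")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def frequencies(self) -> np.ndarray:
        """Realised per-variant alternate-allele frequencies."""
        return self.alleles.mean(axis=0)

    def index_of(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(variant_id)


@dataclass(frozen=True)
class RiskModel:
    """Logistic liability model for the longevity phenotype.

    ``flag_effects`` maps variant id to the per-alternate-allele log-odds of
    being a case; a negative effect on a risk (alternate) allele produces
    the risk-allele depletion pattern in long-lived cases.
    ``haplotype_effects`` adds a per-copy log-odds for tagged haplotypes
    (e.g. a protective low-frequency haplotype enriched in cases).
    """

    flag_effects: dict[str, float] = field(default_factory=dict)
    baseline_logit: float = 0.0
    haplotype_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.baseline_logit, *self.flag_effects.values(),
                *self.haplotype_effects.values()]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("risk model effects must be finite")


@dataclass(frozen=True)
class Pool:
    pool_id: str
    cohort: str  # "case" or "control"
    individual_ids: tuple[int, ...]


@dataclass(frozen=True)
class PoolDesign:
    """Assignment of individuals to sequencing pools."""

    pools: tuple[Pool, ...]
    pool_size: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.pools:
            if p.cohort not in ("case", "control"):
                raise ValueError(f"pool {p.pool_id}: cohort must be case/control")
            if len(p.individual_ids) == 0:
                raise ValueError(f"pool {p.pool_id} is empty")
            dup = seen.intersection(p.individual_ids)
            if dup:
                raise ValueError(f"individuals assigned twice: {sorted(dup)[:5]}")
            seen.update(p.individual_ids)

    @property
    def pool_ids(self) -> list[str]:
        return [p.pool_id for p in self.pools]

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def case_mask(self) -> np.ndarray:
        return np.array([p.cohort == "case" for p in self.pools], dtype=bool)

    def pool_sizes(self) -> np.ndarray:
        return np.array([len(p.individual_ids) for p in self.pools], dtype=int)


@dataclass
class PooledCounts:
    """Per-pool, per-variant sequencing read counts."""

    depths: np.ndarray      # (n_pools, n_variants) int
    alt_counts: np.ndarray  # (n_pools, n_variants) int
    pool_ids: list[str]
    variant_ids: list[str]
    error_rate: float = 0.0
    mean_depth: float | None = None
    true_fractions: np.ndarray | None = None  # simulation truth, optional

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if self.depths.shape != self.alt_counts.shape:
            raise ValueError("depths/alt_counts shape mismatch")
        if (self.depths < 0).any():
            raise ValueError("negative depths")
        if ((self.alt_counts < 0) | (self.alt_counts > self.depths)).any():
            raise ValueError("alt_counts must satisfy 0 <= alt <= depth")

    @property
    def n_pools(self) -> int:
        return self.depths.shape[0]

    @property
    def n_variants(self) -> int:
        return self.depths.shape[1]


@dataclass
class Cohort:
    """Sampled diploid individuals with phenotype labels.

    ``genotypes`` holds per-individual alternate-allele dosages (0/1/2) for
    every panel variant; ``labels`` is 1 for cases.
    """

    genotypes: np.ndarray  # (n_individuals, n_variants) int8
    labels: np.ndarray     # (n_individuals,) 0/1
    variants: list[VariantRecord]
    region: RegionSpec | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def allele_frequencies(self, mask: np.ndarray | None = None) -> np.ndarray:
        g = self.genotypes if mask is None else self.genotypes[mask]
        return g.mean(axis=0) / 2.0


@dataclass(frozen=True)
class FlagSNP:
    """A published trait-associated variant with a designated risk allele."""

    id: str
    trait: str
    risk_allele: str  # "ref" or "alt"


# ---------------------------------------------------------------------------
# allele-frequency spectrum
# ---------------------------------------------------------------------------

# Occupancy of minor-allele-frequency bins observed in deep targeted
# sequencing of a ~230 kb locus in ~1900 chromosomes: the spectrum is
# dominated by rare variants, with a secondary mass of common ones.
DEFAULT_SPECTRUM_BINS: tuple[tuple[float, float], ...] = (
    (0.0005, 0.005),
    (0.005, 0.01),
    (0.01, 0.05),
    (0.05, 0.10),
    (0.10, 0.25),
    (0.25, 0.50),
)
DEFAULT_SPECTRUM_WEIGHTS: tuple[float, ...] = (1307, 144, 311, 108, 115, 231)


def af_spectrum_from_bins(
    bins: Sequence[tuple[float, float]] = DEFAULT_SPECTRUM_BINS,
    weights: Sequence[float] = DEFAULT_SPECTRUM_WEIGHTS,
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Return a sampler drawing allele frequencies uniformly within MAF
    bins, with bins chosen proportionally to ``weights``."""
    lo = np.array([b[0] for b in bins])
    hi = np.array([b[1] for b in bins])
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if (lo <= 0).any() or (hi > 0.5).any():
        raise ValueError("spectrum bins must lie in (0, 0.5]")

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        which = rng.choice(len(w), size=size, p=w)
        return rng.uniform(lo[which], hi[which])

    return sample


def uniform_af_spectrum(low: float, high: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    if not 0 < low <= high <= 0.5:
        raise ValueError("need 0 < low <= high <= 0.5")
    return lambda rng, size: rng.uniform(low, high, size=size)


def constant_af_spectrum(value: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    if not 0 < value <= 0.5:
        raise ValueError("need 0 < value <= 0.5")
    return lambda rng, size: np.full(size, value)


# ---------------------------------------------------------------------------
# haplotype simulation
# ---------------------------------------------------------------------------


def _max_binary_correlation(p: np.ndarray, q: float) -> np.ndarray:
    """Upper bound on the correlation of Bernoulli(p) with Bernoulli(q)
    when the rarer variable is nested in the commoner one."""
    p = np.asarray(p, dtype=float)
    lo = np.minimum(p, q)
    hi = np.maximum(p, q)
    return np.sqrt(lo * (1 - hi) / (hi * (1 - lo)))


def simulate_haplotypes(
    region: RegionSpec,
    ld: LDSpec,
    n_hap: int,
    n_variants: int,
    af_spectrum: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    on_unattainable: Literal["error", "clamp"] = "error",
) -> HaplotypePanel:
    """Simulate a haplotype panel with block-structured LD.

    Variants are placed at distinct random positions, partitioned into
    ``ld.n_blocks`` contiguous blocks, and generated as noisy copies of a
    per-block latent anchor so pairwise within-block r-squared approaches
    ``ld.within_block_r2`` while cross-block variants are independent.

    ``VariantRecord.true_af`` is set to the realised column frequency of
    the emitted matrix, so downstream truth comparisons are exact.
    """
    if n_hap < 2 or n_hap % 2:
        raise ValueError("n_hap must be even and >= 2")
    if n_variants < ld.n_blocks:
        raise ValueError("n_variants must be >= n_blocks")
    rng = np.random.default_rng(seed)
    af_spectrum = af_spectrum or af_spectrum_from_bins()

    positions = np.sort(rng.choice(np.arange(region.start, region.end),
                                   size=n_variants, replace=False))
    if ld.block_boundaries is not None:
        bounds = np.asarray(ld.block_boundaries)
        block_of = np.searchsorted(bounds, positions, side="right")
    else:
        block_of = np.minimum((np.arange(n_variants) * ld.n_blocks) // n_variants,
                              ld.n_blocks - 1)

    target_af = np.clip(af_spectrum(rng, n_variants), 1e-6, 0.5)
    if (target_af <= 0).any() or (target_af > 0.5).any():
        raise ValueError("af_spectrum must yield frequencies in (0, 0.5]")

    # two block-mates are conditionally independent given the anchor, so
    # their correlation is the product of their anchor correlations:
    # pairwise r^2 = s^4, hence s = target^(1/4)
    s_target = ld.within_block_r2 ** 0.25
    alleles = np.empty((n_hap, n_variants), dtype=np.uint8)
    for b in range(ld.n_blocks):
        cols = np.flatnonzero(block_of == b)
        if cols.size == 0:
            continue
        p = target_af[cols]
        q = float(np.median(p))
        q = min(max(q, 1e-4), 0.5)
        smax = _max_binary_correlation(p, q)
        s = np.full(cols.size, s_target)
        bad = s > smax
        if bad.any():
            if on_unattainable == "error":
                raise LDUnattainableError(
                    f"block {b}: within-block r2={ld.within_block_r2} needs "
                    f"anchor correlation {float(s_target):.3f}, unattainable for "
                    f"{int(bad.sum())} variant(s) (max {smax[bad].min():.3f}); "
                    "use on_unattainable='clamp' to ride the background at "
                    "maximal attainable correlation")
            s = np.minimum(s, smax)
        anchor = rng.random(n_hap) < q
        # conditional emission probabilities given anchor state
        d = s * np.sqrt(p * (1 - p)) / math.sqrt(q * (1 - q))
        a = np.clip(p + (1 - q) * d, 0.0, 1.0)
        bb = np.clip(p - q * d, 0.0, 1.0)
        u = rng.random((n_hap, cols.size))
        prob = np.where(anchor[:, None], a[None, :], bb[None, :])
        alleles[:, cols] = (u < prob).astype(np.uint8)

    realized = alleles.mean(axis=0)
    bases = "ACGT"
    variants: list[VariantRecord] = []
    for j in range(n_variants):
        pos = int(positions[j])
        ref = region.base_at(pos) if region.sequence is not None else "A"
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        variants.append(VariantRecord(
            id=f"var{j:05d}", position=pos, ref=ref, alt=alt,
            true_af=float(realized[j]), block=int(block_of[j])))
    return HaplotypePanel(alleles=alleles, variants=variants,
                          haplotype_tags=[None] * n_hap, region=region)


def attach_linked_haplotype_group(
    panel: HaplotypePanel,
    carrier_freq: float,
    n_linked_variants: int,
    anchor_id: str | None = None,
    anchor_allele: Literal["ref", "alt"] = "alt",
    seed: int = 0,
    tag: str = "linked",
    anchors: Sequence[tuple[str, str]] | None = None,
    min_matches: int | None = None,
) -> HaplotypePanel:
    """Add a group of mutually linked low-frequency variants riding on a
    carrier sub-haplotype.

    The carrier background is defined either by a single anchor allele
    (``anchor_id`` + ``anchor_allele``) or by a combination: ``anchors``
    is a list of (variant id, allele) pairs and a haplotype qualifies as
    a potential carrier when it matches at least ``min_matches`` of them
    (default: all).  The combined form models a haplotype that carries
    the risk (or non-risk) alleles of several flag variants at once.

    The new variants share a single carrier set (a random subset of the
    qualifying haplotypes of size carrier_freq * n_hap), so they are in
    near-perfect mutual LD and positively linked to the anchor allele(s).
    Returns a new panel; the input is not modified.
    """
    if not 0 < carrier_freq < 0.05:
        raise ValueError("carrier_freq must be in (0, 0.05) — low-frequency group")
    if anchors is None:
        if anchor_id is None:
            raise ValueError("need anchor_id or anchors")
        anchors = [(anchor_id, anchor_allele)]
    if min_matches is None:
        min_matches = len(anchors)
    matches = np.zeros(panel.n_hap, dtype=int)
    for aid, allele in anchors:
        if allele not in ("ref", "alt"):
            raise ValueError("anchor allele must be 'ref' or 'alt'")
        col = panel.alleles[:, panel.index_of(aid)]
        matches += (col == (1 if allele == "alt" else 0))
    carriers_of_allele = np.flatnonzero(matches >= min_matches)
    n_new_carriers = int(round(carrier_freq * panel.n_hap))
    if n_new_carriers > carriers_of_allele.size:
        raise ValueError(
            f"carrier_freq {carrier_freq} exceeds the frequency of the "
            f"anchor background ({carriers_of_allele.size / panel.n_hap:.3f})")
    tags = list(panel.haplotype_tags or [None] * panel.n_hap)
    if n_linked_variants == 0:
        return HaplotypePanel(panel.alleles.copy(), list(panel.variants),
                              tags, panel.region)

    rng = np.random.default_rng(seed)
    # prefer untagged haplotypes: linked groups model distinct ancestral
    # backgrounds, so a haplotype should not carry two group tags
    untagged = np.array([h for h in carriers_of_allele if tags[h] is None])
    pool_hap = untagged if untagged.size >= n_new_carriers else carriers_of_allele
    carrier_set = rng.choice(pool_hap, size=n_new_carriers, replace=False)
    new_col = np.zeros(panel.n_hap, dtype=np.uint8)
    new_col[carrier_set] = 1
    for h in carrier_set:
        tags[h] = tag

    region = panel.region
    taken = {v.position for v in panel.variants}
    if region is not None:
        lo, hi = region.start, region.end
    else:
        lo = min(taken) if taken else 0
        hi = max(taken) + n_linked_variants + 1 if taken else n_linked_variants
    free = np.setdiff1d(np.arange(lo, hi), np.fromiter(taken, int, len(taken)))
    pos_new = np.sort(rng.choice(free, size=n_linked_variants, replace=False))

    anchor_block = panel.variants[panel.index_of(anchors[0][0])].block
    bases = "ACGT"
    new_vars: list[VariantRecord] = []
    for k in range(n_linked_variants):
        pos = int(pos_new[k])
        ref = region.base_at(pos) if region is not None and region.sequence is not None else "A"
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        new_vars.append(VariantRecord(
            id=f"{tag}{k:03d}", position=pos, ref=ref, alt=alt,
            true_af=n_new_carriers / panel.n_hap, block=anchor_block,
            haplotype_tag=tag))

    alleles = np.concatenate(
        [panel.alleles, np.repeat(new_col[:, None], n_linked_variants, axis=1)],
        axis=1)
    variants = list(panel.variants) + new_vars
    order = np.argsort([v.position for v in variants], kind="stable")
    return HaplotypePanel(alleles[:, order], [variants[i] for i in order],
                          tags, region)


# ---------------------------------------------------------------------------
# phenotypes and pooling
# ---------------------------------------------------------------------------


def _case_probabilities(
    panel: HaplotypePanel, model: RiskModel, h1: np.ndarray, h2: np.ndarray
) -> np.ndarray:
    logit = np.full(h1.shape[0], model.baseline_logit)
    for vid, beta in model.flag_effects.items():
        col = panel.alleles[:, panel.index_of(vid)]
        logit += beta * (col[h1].astype(float) + col[h2].astype(float))
    if model.haplotype_effects:
        tags = np.array([t or "" for t in (panel.haplotype_tags or [])])
        for tag, beta in model.haplotype_effects.items():
            dose = (tags[h1] == tag).astype(float) + (tags[h2] == tag).astype(float)
            logit += beta * dose
    return 1.0 / (1.0 + np.exp(-logit))


def assign_phenotypes(
    panel: HaplotypePanel,
    model: RiskModel,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    max_draw_factor: int = 2000,
) -> Cohort:
    """Sample diploid individuals (haplotype pairs with replacement, HWE)
    and phenotype them under the logistic risk model until both cohort
    quotas are filled.  Deterministic given the seed."""
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    want = n_cases + n_controls
    case_pairs = np.empty((0, 2), dtype=np.int64)
    ctrl_pairs = np.empty((0, 2), dtype=np.int64)
    drawn = 0
    while len(case_pairs) < n_cases or len(ctrl_pairs) < n_controls:
        if drawn > max_draw_factor * want:
            raise RuntimeError(
                "phenotype quotas unattainable under this risk model "
                f"(cases {len(case_pairs)}/{n_cases}, controls "
                f"{len(ctrl_pairs)}/{n_controls} after {drawn} draws)")
        m = max(want, 1000)
        h = rng.integers(panel.n_hap, size=(m, 2))
        p = _case_probabilities(panel, model, h[:, 0], h[:, 1])
        if not (np.all(np.isfinite(p)) and np.all((p > 0) & (p < 1))):
            # a probability of exactly 0/1 makes one quota unreachable in
            # the degenerate direction only; tolerate unless stuck (above)
            p = np.clip(p, 1e-12, 1 - 1e-12)
        is_case = rng.random(m) < p
        drawn += m
        case_pairs = np.concatenate([case_pairs, h[is_case]])[:n_cases + m]
        ctrl_pairs = np.concatenate([ctrl_pairs, h[~is_case]])[:n_controls + m]
    pairs = np.concatenate([case_pairs[:n_cases], ctrl_pairs[:n_controls]])
    labels = np.concatenate([np.ones(n_cases, dtype=np.int8),
                             np.zeros(n_controls, dtype=np.int8)])
    genotypes = (panel.alleles[pairs[:, 0]].astype(np.int8)
                 + panel.alleles[pairs[:, 1]].astype(np.int8))
    return Cohort(genotypes=genotypes, labels=labels,
                  variants=list(panel.variants), region=panel.region)


def expected_frequency_difference(beta: float, af: float,
                                  baseline_logit: float = 0.0) -> float:
    """Analytic expectation of the case-minus-control alternate-allele
    frequency for a single-variant logistic model under HWE, by direct
    summation over the three genotype classes.  Serves as an oracle for
    ``assign_phenotypes``."""
    g = np.array([0.0, 1.0, 2.0])
    pg = np.array([(1 - af) ** 2, 2 * af * (1 - af), af ** 2])
    w = 1.0 / (1.0 + np.exp(-(baseline_logit + beta * g)))
    f_case = float(np.sum(g * pg * w) / (2 * np.sum(pg * w)))
    f_ctrl = float(np.sum(g * pg * (1 - w)) / (2 * np.sum(pg * (1 - w))))
    return f_case - f_ctrl


def build_pool_design(
    cohort: Cohort,
    n_case_pools: int = 18,
    n_control_pools: int = 20,
    pool_size: int = 25,
    seed: int = 0,
) -> PoolDesign:
    """Partition individuals into equal-size pools per cohort.  Assignment
    order is a seedable permutation (pool construction is otherwise
    arbitrary)."""
    rng = np.random.default_rng(seed)
    case_ids = np.flatnonzero(cohort.labels == 1)
    ctrl_ids = np.flatnonzero(cohort.labels == 0)
    if case_ids.size != n_case_pools * pool_size:
        raise ValueError("case count does not match pool geometry")
    if ctrl_ids.size != n_control_pools * pool_size:
        raise ValueError("control count does not match pool geometry")
    case_ids = rng.permutation(case_ids)
    ctrl_ids = rng.permutation(ctrl_ids)
    pools = []
    for k in range(n_case_pools):
        pools.append(Pool(f"case{k + 1:02d}", "case",
                          tuple(int(i) for i in case_ids[k * pool_size:(k + 1) * pool_size])))
    for k in range(n_control_pools):
        pools.append(Pool(f"ctrl{k + 1:02d}", "control",
                          tuple(int(i) for i in ctrl_ids[k * pool_size:(k + 1) * pool_size])))
    return PoolDesign(pools=tuple(pools), pool_size=pool_size)


def simulate_pooled_reads(
    cohort: Cohort,
    design: PoolDesign,
    mean_depth: float = 30.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> PooledCounts:
    """Simulate per-pool read counts at every variant.

    Depth per pool-variant cell is Poisson(mean_depth) truncated below at 1
    (variant sites are, by construction, covered); alternate-supporting
    reads are Binomial(depth, f') with f' = f(1-e) + (1-f)e where f is the
    pool's true alternate-chromosome fraction and e the per-read
    substitution error rate."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    for p in design.pools:
        for i in p.individual_ids:
            if i < 0 or i >= cohort.n_individuals:
                raise ValueError(f"pool {p.pool_id}: unknown individual {i}")
    rng = np.random.default_rng(seed)
    n_pools = design.n_pools
    n_var = cohort.genotypes.shape[1]
    true_f = np.empty((n_pools, n_var))
    for k, p in enumerate(design.pools):
        idx = np.asarray(p.individual_ids)
        true_f[k] = cohort.genotypes[idx].sum(axis=0) / (2.0 * idx.size)
    depths = rng.poisson(mean_depth, size=(n_pools, n_var))
    depths = np.maximum(depths, 1)
    f_obs = true_f * (1 - error_rate) + (1 - true_f) * error_rate
    alt = rng.binomial(depths, f_obs)
    return PooledCounts(depths=depths, alt_counts=alt,
                        pool_ids=design.pool_ids,
                        variant_ids=[v.id for v in cohort.variants],
                        error_rate=error_rate, mean_depth=mean_depth,
                        true_fractions=true_f)


# ---------------------------------------------------------------------------
# default study scenario
# ---------------------------------------------------------------------------


def default_region(seed: int = 0) -> RegionSpec:
    """A stylised model of the 230 kb 9p21.3 GWAS interval
    (chr9:21,950,000-22,180,000, hg19) with a simplified plus-strand gene
    model: two protein-coding tumour-suppressor genes (CDKN2A, CDKN2B) and
    a long noncoding transcript (ANRIL) spanning much of the locus.
    Coordinates are synthetic stand-ins, not the real exon structure."""
    rng = np.random.default_rng(seed)
    start, end = 21_950_000, 22_180_000
    seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=end - start)])
    features = (
        # CDKN2A: 3 CDS exons (total length divisible by 3) + UTRs
        GeneFeature("CDKN2A", "UTR5", 21_967_000, 21_967_200),
        GeneFeature("CDKN2A", "CDS", 21_967_200, 21_967_500, frame=0),
        GeneFeature("CDKN2A", "intron", 21_967_500, 21_970_000),
        GeneFeature("CDKN2A", "CDS", 21_970_000, 21_970_300, frame=0),
        GeneFeature("CDKN2A", "intron", 21_970_300, 21_974_000),
        GeneFeature("CDKN2A", "CDS", 21_974_000, 21_974_300, frame=0),
        GeneFeature("CDKN2A", "UTR3", 21_974_300, 21_975_000),
        # CDKN2B: 2 CDS exons
        GeneFeature("CDKN2B", "UTR5", 22_002_000, 22_002_100),
        GeneFeature("CDKN2B", "CDS", 22_002_100, 22_002_400, frame=0),
        GeneFeature("CDKN2B", "intron", 22_002_400, 22_008_000),
        GeneFeature("CDKN2B", "CDS", 22_008_000, 22_008_300, frame=0),
        GeneFeature("CDKN2B", "UTR3", 22_008_300, 22_008_800),
        # ANRIL: noncoding exons with long introns across the GWAS interval
        GeneFeature("ANRIL", "noncoding_exon", 22_020_000, 22_020_500),
        GeneFeature("ANRIL", "intron", 22_020_500, 22_050_000),
        GeneFeature("ANRIL", "noncoding_exon", 22_050_000, 22_050_400),
        GeneFeature("ANRIL", "intron", 22_050_400, 22_090_000),
        GeneFeature("ANRIL", "noncoding_exon", 22_090_000, 22_090_600),
        GeneFeature("ANRIL", "intron", 22_090_600, 22_120_000),
        GeneFeature("ANRIL", "noncoding_exon", 22_120_000, 22_120_300),
    )
    return RegionSpec("chr9", start, end, features, seq)


DEFAULT_FLAGS: tuple[tuple[str, str, str, float, float], ...] = (
    # (id, trait, risk allele, population AF of the alt allele, log-odds)
    ("rs1333049", "coronary_artery_disease", "alt", 0.45, -0.25),
    ("rs10811661", "type_2_diabetes", "alt", 0.30, -0.25),
    ("rs4977756", "glaucoma", "alt", 0.40, -0.25),
    ("rs1412829", "glioma", "ref", 0.35, -0.25),
    ("rs1063192", "cancer", "alt", 0.45, -0.25),
)


@dataclass
class Scenario:
    """A fully simulated pooled study: panel, cohort, design, read counts
    and the auxiliary truth tables the pipeline consumes."""

    region: RegionSpec
    panel: HaplotypePanel
    cohort: Cohort
    design: PoolDesign
    counts: PooledCounts
    model: RiskModel
    flags: list[FlagSNP]
    known_ids: list[str]


def default_scenario(
    seed: int = 0,
    n_variants: int = 2000,
    n_hap: int = 2000,
    n_cases: int = 450,
    n_controls: int = 500,
    n_case_pools: int = 18,
    n_control_pools: int = 20,
    pool_size: int = 25,
    mean_depth: float = 750.0,
    error_rate: float = 0.001,
    within_block_r2: float = 0.1,
    risk_group_size: int = 150,
    risk_carrier_freq: float = 0.045,
    risk_effect: float = 0.9,
    protective_group_size: int = 50,
    protective_carrier_freq: float = 0.03,
    protective_effect: float = 2.2,
    flag_beta: float = -0.25,
    with_linked_groups: bool = True,
    with_effects: bool = True,
) -> Scenario:
    """Simulate the default study: a 230 kb region with ~2000 variants in 5
    LD blocks, five flagged GWAS risk variants with modest protective
    effects in cases, two low-frequency linked variant groups riding on
    risk and non-risk backgrounds, 450 cases in 18 pools and 500 controls
    in 20 pools at 30x mean depth.

    ``with_effects=False`` yields a null cohort (all effects zero) with the
    same genetic structure."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(2 ** 31, size=8)
    region = default_region(seed=int(sub[0]))
    ld = LDSpec(n_blocks=5, within_block_r2=within_block_r2)
    panel = simulate_haplotypes(region, ld, n_hap=n_hap, n_variants=n_variants,
                                seed=int(sub[1]), on_unattainable="clamp")

    # plant the five flag variants, one per LD block, replacing the common
    # variant nearest the block centre so each flag inherits block LD
    flags: list[FlagSNP] = []
    freqs = panel.frequencies()
    for b, (fid, trait, risk, af, _) in enumerate(DEFAULT_FLAGS):
        cols = [i for i, v in enumerate(panel.variants) if v.block == b]
        common = [i for i in cols if 0.05 <= freqs[i] <= 0.5]
        j = common[len(common) // 2] if common else cols[len(cols) // 2]
        # resample the column to the flag's population frequency, keeping
        # its anchor linkage by blending with the existing column
        col = panel.alleles[:, j].astype(bool)
        target_n = int(round(af * panel.n_hap))
        have = int(col.sum())
        if have < target_n:
            off = np.flatnonzero(~col)
            add = np.random.default_rng(int(sub[2]) + b).choice(
                off, size=target_n - have, replace=False)
            col[add] = True
        elif have > target_n:
            on = np.flatnonzero(col)
            drop = np.random.default_rng(int(sub[2]) + b).choice(
                on, size=have - target_n, replace=False)
            col[drop] = False
        panel.alleles[:, j] = col.astype(np.uint8)
        v = panel.variants[j]
        beta = flag_beta if with_effects else 0.0
        panel.variants[j] = dataclasses.replace(
            v, id=fid, true_af=float(col.mean()), risk_allele=risk,
            trait=trait, beta=beta if risk == "alt" else -beta)
        flags.append(FlagSNP(fid, trait, risk))

    if with_linked_groups:
        # the groups ride combined-risk / combined-non-risk backgrounds:
        # carriers match the risk (resp. non-risk) allele at >= 4 of the
        # 5 flags, so group frequencies track every flag's risk allele
        risk_anchors = [(f.id, f.risk_allele) for f in flags]
        nonrisk_anchors = [(f.id, "ref" if f.risk_allele == "alt" else "alt")
                           for f in flags]
        panel = attach_linked_haplotype_group(
            panel, carrier_freq=risk_carrier_freq,
            n_linked_variants=risk_group_size, anchors=risk_anchors,
            min_matches=4, seed=int(sub[3]), tag="risk_hap")
        panel = attach_linked_haplotype_group(
            panel, carrier_freq=protective_carrier_freq,
            n_linked_variants=protective_group_size, anchors=nonrisk_anchors,
            min_matches=4, seed=int(sub[4]), tag="protective_hap")

    flag_effects = {v.id: v.beta for v in panel.variants
                    if v.risk_allele is not None}
    hap_effects = {}
    if with_linked_groups and with_effects:
        hap_effects = {"risk_hap": -risk_effect,
                       "protective_hap": +protective_effect}
    if not with_effects:
        flag_effects = {k: 0.0 for k in flag_effects}
    model = RiskModel(flag_effects=flag_effects, baseline_logit=0.0,
                      haplotype_effects=hap_effects)

    cohort = assign_phenotypes(panel, model, n_cases, n_controls,
                               seed=int(sub[5]))
    design = build_pool_design(cohort, n_case_pools, n_control_pools,
                               pool_size, seed=int(sub[6]))
    counts = simulate_pooled_reads(cohort, design, mean_depth, error_rate,
                                   seed=int(sub[7]))
    # known-ID list: flags plus a random 60% of the non-flag variants,
    # emulating a database that misses a third of locus variants
    id_rng = np.random.default_rng(seed + 101)
    others = [v.id for v in panel.variants if v.risk_allele is None
              and v.haplotype_tag is None]
    n_known = int(0.6 * len(others))
    known = sorted(id_rng.choice(others, size=n_known, replace=False))
    known_ids = [f.id for f in flags] + list(known)
    return Scenario(region=region, panel=panel, cohort=cohort, design=design,
                    counts=counts, model=model, flags=flags,
                    known_ids=known_ids)


# ---------------------------------------------------------------------------
# writers (text formats consumed by the I/O layer)
# ---------------------------------------------------------------------------


def write_vcf(counts: PooledCounts, variants: list[VariantRecord],
              region: RegionSpec, path: str) -> None:
    """Write pooled counts as a VCF 4.2 file with one sample column per
    pool, carrying AD (ref,alt read counts) and DP."""
    by_id = {v.id: v for v in variants}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={region.chrom},length={region.end}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(counts.pool_ids) + "\n")
        for j, vid in enumerate(counts.variant_ids):
            v = by_id[vid]
            cells = []
            for k in range(counts.n_pools):
                d = int(counts.depths[k, j])
                a = int(counts.alt_counts[k, j])
                cells.append(f"{d - a},{a}:{d}")
            fh.write(f"{region.chrom}\t{v.position + 1}\t{v.id}\t{v.ref}\t"
                     f"{v.alt}\t.\tPASS\t.\tAD:DP\t" + "\t".join(cells) + "\n")


def write_pool_design(design: PoolDesign, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("pool_id\tcohort\tn_individuals\n")
        for p in design.pools:
            fh.write(f"{p.pool_id}\t{p.cohort}\t{len(p.individual_ids)}\n")


def write_ground_truth(panel: HaplotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tposition\ttrue_af\trisk_allele\ttrait\tbeta\t"
                 "block\thaplotype_tag\n")
        for v in panel.variants:
            fh.write(f"{v.id}\t{v.position}\t{v.true_af:.6f}\t"
                     f"{v.risk_allele or '.'}\t{v.trait or '.'}\t{v.beta}\t"
                     f"{v.block if v.block is not None else '.'}\t"
                     f"{v.haplotype_tag or '.'}\n")


def write_flag_snps(flags: Sequence[FlagSNP], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\ttrait\trisk_allele\n")
        for f in flags:
            fh.write(f"{f.id}\t{f.trait}\t{f.risk_allele}\n")


def write_known_ids(ids: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\n")
        for i in ids:
            fh.write(f"{i}\n")


def write_regions_bed(region: RegionSpec, path: str,
                      intervals: Sequence[tuple[str, int, int]] | None = None) -> None:
    """Write named analysis intervals as BED (0-based half-open).  By
    default, one interval per gene span plus the flanking subregions."""
    if intervals is None:
        spans: dict[str, list[int]] = {}
        for f in region.gene_features:
            spans.setdefault(f.gene, [f.start, f.end])
            spans[f.gene][0] = min(spans[f.gene][0], f.start)
            spans[f.gene][1] = max(spans[f.gene][1], f.end)
        intervals = [(g, s, e) for g, (s, e) in sorted(spans.items(),
                                                       key=lambda kv: kv[1][0])]
        # downstream interval after the last coding gene, a recurrent
        # regulatory neighbourhood in this locus
        intervals.append(("CDKN2A_downstream", 21_975_000, 22_002_000))
    with open(path, "w") as fh:
        for name, s, e in intervals:
            fh.write(f"{region.chrom}\t{s}\t{e}\t{name}\n")
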