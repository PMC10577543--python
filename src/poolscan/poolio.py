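"""Pooled-count input, allele-frequency estimation and variant summaries.

Pool-seq data yield read counts, not genotypes: the per-pool alternate
allele frequency is estimated as alt/depth, and cohort-level frequencies
are averages over pools weighted by chromosome count (2 x pool size).
Minor-allele counts (MAC) are reconstructed as rounded dosages on the
combined cohorts, which is as close as pooled data come to the integer
allele counts of individual-level studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .simcohort import (
    FUNCTIONAL_CLASSES,
    PoolDesign,
    PooledCounts,
    RegionSpec,
    VariantRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "FrequencyMatrix",
    "SummaryTable",
    "MAF_BIN_EDGES",
    "MAF_BIN_LABELS",
    "REFERENCE_BIN_COUNTS",
    "REFERENCE_FUNCTIONAL_COUNTS",
    "read_pooled_vcf",
    "read_pool_design",
    "estimate_frequencies",
    "flag_novelty",
    "load_known_ids",
    "load_flag_snps",
    "classify_functional",
    "summarize_variants",
    "concordance",
    "percentage",
]

# Half-open MAF bins; the last bin is closed at 0.5.
MAF_BIN_EDGES = (0.0, 0.005, 0.01, 0.05, 0.10, 0.25, 0.50)
MAF_BIN_LABELS = ("0%-0.5%", "0.5%-1%", "1%-5%", "5%-10%", "10%-25%", "25%-50%")

# Variant counts by MAF bin from the pooled targeted-sequencing study of
# the 9p21.3 locus in 450 centenarians and 500 controls (dbSNP-149
# annotation).  Columns: (SNP known, SNP novel, complex known, complex
# novel); rows follow MAF_BIN_LABELS.  Used as printed-table input for the
# summary arithmetic and its consistency checks.
REFERENCE_BIN_COUNTS = pd.DataFrame(
    [
        [557, 664, 39, 47],
        [109, 29, 3, 3],
        [259, 21, 20, 11],
        [93, 0, 10, 5],
        [99, 0, 11, 5],
        [225, 0, 6, 0],
    ],
    index=list(MAF_BIN_LABELS),
    columns=pd.MultiIndex.from_product([["SNP", "complex"], ["known", "novel"]]),
)

# Functional annotation counts for the same study's variants with at least
# four minor-allele counts, plus the printed singleton tally among novel
# variants.
REFERENCE_FUNCTIONAL_COUNTS = {
    "annotated_total": 1291,
    "intronic": 720,
    "intergenic": 526,
    "exonic": 45,
    "novel_singletons": 616,
}


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """A percentage rounded to a fixed number of decimals (the convention
    used throughout the summary tables)."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round(100.0 * count / total, decimals)


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------


def read_pool_design(path: str) -> PoolDesign:
    """Read a pool-design TSV (pool_id, cohort, n_individuals).  Individual
    ids are synthesised sequentially; only the pool->cohort map and sizes
    matter downstream."""
    df = pd.read_csv(path, sep="\t")
    from .simcohort import Pool

    pools = []
    nxt = 0
    for _, row in df.iterrows():
        n = int(row["n_individuals"])
        pools.append(Pool(str(row["pool_id"]), str(row["cohort"]),
                          tuple(range(nxt, nxt + n))))
        nxt += n
    sizes = {len(p.individual_ids) for p in pools}
    pool_size = sizes.pop() if len(sizes) == 1 else max(
        len(p.individual_ids) for p in pools)
    return PoolDesign(pools=tuple(pools), pool_size=pool_size)


def read_pooled_vcf(path: str, design: PoolDesign) -> PooledCounts:
    """Read a pooled VCF (one sample per pool, AD per-allele depths) into a
    counts matrix aligned to the design's pool order.  Multi-allelic
    records are split into biallelic rows with position-preserving ids."""
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    missing = [p for p in design.pool_ids if p not in samples]
    if missing:
        raise ValueError(f"pools absent from VCF: {missing}")
    extra = [s for s in samples if s not in set(design.pool_ids)]
    if extra:
        raise ValueError(f"VCF pools absent from design: {extra}")
    order = [samples.index(p) for p in design.pool_ids]

    depths_rows: list[list[int]] = []
    alt_rows: list[list[int]] = []
    ids: list[str] = []
    for rec in vf:
        alts = rec.alts or ()
        sample_ads = []
        for s in rec.samples.values():
            ad = s.get("AD")
            if ad is None or any(a is None for a in ad):
                raise ValueError(f"record {rec.id or rec.pos}: AD field missing")
            sample_ads.append(ad)
        for ai in range(len(alts)):
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            if len(alts) > 1:
                rid = f"{rid}_{ai + 1}"
            ids.append(rid)
            d_row, a_row = [], []
            for si in order:
                ad = sample_ads[si]
                a = int(ad[ai + 1])
                d = int(ad[0]) + a  # biallelic depth: ref + this alt
                d_row.append(d)
                a_row.append(a)
            depths_rows.append(d_row)
            alt_rows.append(a_row)
    n_pools = design.n_pools
    if ids:
        depths = np.array(depths_rows).T
        alt = np.array(alt_rows).T
    else:
        depths = np.zeros((n_pools, 0), dtype=int)
        alt = np.zeros((n_pools, 0), dtype=int)
    return PooledCounts(depths=depths, alt_counts=alt,
                        pool_ids=list(design.pool_ids), variant_ids=ids)


# ---------------------------------------------------------------------------
# frequency estimation
# ---------------------------------------------------------------------------


@dataclass
class FrequencyMatrix:
    """Pools x variants alternate-allele frequency estimates.

    ``freqs`` holds NaN where a pool had zero depth.  ``af`` is the
    pool-size-weighted combined-cohort alternate frequency; ``maf``/``mac``
    are the minor-allele frequency and its rounded dosage count over all
    2N chromosomes.
    """

    freqs: np.ndarray          # (n_pools, n_variants), NaN = missing
    pool_ids: list[str]
    variant_ids: list[str]
    pool_sizes: np.ndarray
    af: np.ndarray             # combined alternate-allele frequency
    maf: np.ndarray
    mac: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @property
    def n_pools(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_variants(self) -> int:
        return self.freqs.shape[1]

    @property
    def n_chromosomes(self) -> int:
        return int(2 * self.pool_sizes.sum())

    def column(self, variant_id: str) -> np.ndarray:
        return self.freqs[:, self.variant_ids.index(variant_id)]

    def cohort_frequency(self, design: PoolDesign, cohort: str) -> np.ndarray:
        """Pool-size-weighted alternate frequency within one cohort,
        ignoring missing pools per variant."""
        mask = np.array([p.cohort == cohort for p in design.pools])
        return _weighted_freq(self.freqs[mask], self.pool_sizes[mask])

    def minor_freqs(self) -> np.ndarray:
        """Per-pool frequencies oriented to the combined-cohort minor
        allele."""
        flip = self.af > 0.5
        out = self.freqs.copy()
        out[:, flip] = 1.0 - out[:, flip]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=self.pool_ids,
                            columns=self.variant_ids)


def _weighted_freq(freqs: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    w = (2.0 * sizes)[:, None] * np.isfinite(freqs)
    num = np.nansum(freqs * w, axis=0)
    den = w.sum(axis=0)
    out = np.full(freqs.shape[1], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def estimate_frequencies(
    counts: PooledCounts,
    design: PoolDesign,
    max_missing_frac: float = 0.2,
    error_rate: float | None = None,
) -> FrequencyMatrix:
    """Estimate per-pool and combined allele frequencies from read counts.

    Pool frequency is alt/depth; zero-depth cells are flagged missing, and
    a variant is dropped when more than ``max_missing_frac`` of pools are
    missing.  If ``error_rate`` is given, the estimator de-convolves the
    flat substitution error: f = (p - e) / (1 - 2e), clipped to [0, 1].
    By default no correction is applied (the error rate of real data is
    unknown); the raw estimate is then unbiased for the error-convolved
    frequency f' = f(1-e) + (1-f)e, not for f itself.
    """
    if counts.n_pools != design.n_pools:
        raise ValueError("counts/design shape mismatch")
    if counts.pool_ids != design.pool_ids:
        raise ValueError("counts/design pool order mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(counts.depths > 0,
                         counts.alt_counts / np.maximum(counts.depths, 1),
                         np.nan)
    if error_rate is not None:
        if not 0 <= error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        freqs = np.clip((freqs - error_rate) / (1 - 2 * error_rate), 0.0, 1.0)
    missing_frac = np.mean(~np.isfinite(freqs), axis=0)
    keep = missing_frac <= max_missing_frac
    dropped = [vid for vid, k in zip(counts.variant_ids, keep) if not k]
    if dropped:
        log.info("dropping %d variants with >%.0f%% missing pools",
                 len(dropped), 100 * max_missing_frac)
    freqs = freqs[:, keep]
    variant_ids = [vid for vid, k in zip(counts.variant_ids, keep) if k]
    sizes = design.pool_sizes()
    af = _weighted_freq(freqs, sizes)
    maf = np.minimum(af, 1.0 - af)
    n_chrom = int(2 * sizes.sum())
    mac = np.rint(maf * n_chrom).astype(int)
    return FrequencyMatrix(freqs=freqs, pool_ids=list(counts.pool_ids),
                           variant_ids=variant_ids, pool_sizes=sizes,
                           af=af, maf=maf, mac=mac, dropped=dropped)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def load_known_ids(path: str) -> set[str]:
    df = pd.read_csv(path, sep="\t")
    col = "id" if "id" in df.columns else df.columns[0]
    return set(df[col].astype(str))


def load_flag_snps(path: str):
    from .simcohort import FlagSNP

    df = pd.read_csv(path, sep="\t")
    return [FlagSNP(str(r["id"]), str(r["trait"]), str(r["risk_allele"]))
            for _, r in df.iterrows()]


def flag_novelty(variants: list[VariantRecord],
                 known_ids: set[str]) -> list[VariantRecord]:
    """Mark each variant known iff its id appears in the database id list.
    Novelty is a pure id lookup, never inferred from frequency."""
    import dataclasses

    return [dataclasses.replace(v, known=v.id in known_ids) for v in variants]


def _spliced_cds(region: RegionSpec, gene: str) -> tuple[str, dict[int, int]]:
    """Concatenated CDS sequence of a gene and a map from genomic position
    to CDS coordinate (plus strand)."""
    cds = [f for f in region.gene_features
           if f.gene == gene and f.feature_class == "CDS"]
    cds.sort(key=lambda f: f.start)
    seq_parts: list[str] = []
    pos_map: dict[int, int] = {}
    offset = 0
    for f in cds:
        if f.frame:
            # frame shifts are folded into the global CDS coordinate
            pass
        seq_parts.append(region.sequence[f.start - region.start:f.end - region.start])
        for p in range(f.start, f.end):
            pos_map[p] = offset + (p - f.start)
        offset += f.end - f.start
    seq = "".join(seq_parts)
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length of {gene} not divisible by 3")
    return seq, pos_map


def classify_functional(variants: list[VariantRecord],
                        region: RegionSpec) -> list[VariantRecord]:
    """Assign a functional class per variant from the region's gene model.

    Precedence when a position overlaps several features:
    CDS consequence (nonsynonymous vs synonymous by codon translation)
    > UTR > noncoding exon > intron > intergenic.  Non-SNP variants in CDS
    are called nonsynonymous (length-changing).
    """
    import dataclasses

    from Bio.Seq import Seq

    if region.sequence is None:
        raise ValueError("functional classification requires a reference sequence")
    cds_cache: dict[str, tuple[str, dict[int, int]]] = {}
    for f in region.gene_features:
        if f.feature_class == "CDS" and f.gene not in cds_cache:
            cds_cache[f.gene] = _spliced_cds(region, f.gene)

    rank = {"CDS": 0, "UTR5": 1, "UTR3": 1, "noncoding_exon": 2, "intron": 3}
    out = []
    for v in variants:
        hits = [f for f in region.gene_features if f.start <= v.position < f.end]
        if not hits:
            out.append(dataclasses.replace(v, functional_class="intergenic"))
            continue
        best = min(hits, key=lambda f: rank[f.feature_class])
        if best.feature_class == "CDS":
            if v.vclass != "SNP":
                fc = "nonsynonymous"
            else:
                seq, pos_map = cds_cache[best.gene]
                ci = pos_map[v.position]
                codon_i = ci // 3
                codon = list(seq[3 * codon_i:3 * codon_i + 3])
                aa_ref = str(Seq("".join(codon)).translate())
                codon[ci % 3] = v.alt
                aa_alt = str(Seq("".join(codon)).translate())
                fc = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        elif best.feature_class in ("UTR5", "UTR3"):
            fc = "UTR"
        elif best.feature_class == "noncoding_exon":
            fc = "noncoding_exonic"
        else:
            fc = "intronic"
        out.append(dataclasses.replace(v, functional_class=fc))
    return out


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------


def maf_bin_index(maf: np.ndarray) -> np.ndarray:
    """Bin index for each MAF; bins are half-open except the last, which is
    closed at 0.5.  Every MAF in [0, 0.5] falls in exactly one bin."""
    maf = np.asarray(maf, dtype=float)
    if (maf < 0).any() or (maf > 0.5).any():
        raise ValueError("MAF must lie in [0, 0.5]")
    idx = np.searchsorted(MAF_BIN_EDGES[1:], maf, side="right")
    return np.minimum(idx, len(MAF_BIN_LABELS) - 1)


@dataclass
class SummaryTable:
    """Variant counts by MAF bin x class x novelty, plus functional counts
    and singleton tallies.  Percentages are always recomputed from counts.
    """

    bin_counts: pd.DataFrame  # rows = MAF bins, columns = (class, novelty)
    functional_counts: pd.Series | None = None
    n_singletons: int = 0
    n_novel_singletons: int = 0
    mac_threshold: int = 4

    @classmethod
    def from_counts(cls, bin_counts: pd.DataFrame,
                    functional_counts: pd.Series | None = None,
                    n_singletons: int = 0,
                    n_novel_singletons: int = 0) -> "SummaryTable":
        bc = bin_counts.astype(int)
        if (bc.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        return cls(bin_counts=bc, functional_counts=functional_counts,
                   n_singletons=n_singletons,
                   n_novel_singletons=n_novel_singletons)

    # --- totals (always derived from cells) ---
    @property
    def total(self) -> int:
        return int(self.bin_counts.to_numpy().sum())

    def class_total(self, vclass: str) -> int:
        return int(self.bin_counts[vclass].to_numpy().sum())

    def novelty_total(self, novelty: str) -> int:
        return int(self.bin_counts.xs(novelty, axis=1, level=1).to_numpy().sum())

    @property
    def novel_rare(self) -> int:
        """Novel variants with MAF < 1% (the first two bins)."""
        nv = self.bin_counts.xs("novel", axis=1, level=1)
        return int(nv.iloc[:2].to_numpy().sum())

    def pct_novel(self) -> float:
        return percentage(self.novelty_total("novel"), self.total)

    def pct_novel_rare(self) -> float:
        return percentage(self.novel_rare, self.novelty_total("novel"), 0)

    def pct_novel_singletons(self) -> float:
        return percentage(self.n_novel_singletons, self.novelty_total("novel"), 0)

    def functional_pct(self, klass: str) -> float:
        if self.functional_counts is None:
            raise ValueError("no functional counts")
        return percentage(int(self.functional_counts[klass]),
                          int(self.functional_counts.sum()))

    def to_json_dict(self) -> dict:
        d = {
            "total": self.total,
            "snp_total": self.class_total("SNP"),
            "complex_total": self.class_total("complex"),
            "novel_total": self.novelty_total("novel"),
            "novel_rare": self.novel_rare,
            "pct_novel": self.pct_novel(),
            "n_singletons": self.n_singletons,
            "n_novel_singletons": self.n_novel_singletons,
            "bins": {
                lbl: {f"{c}_{n}": int(self.bin_counts.loc[lbl, (c, n)])
                      for c in ("SNP", "complex") for n in ("known", "novel")}
                for lbl in self.bin_counts.index
            },
        }
        if self.functional_counts is not None:
            d["functional"] = {k: int(v)
                               for k, v in self.functional_counts.items()}
        return d


def summarize_variants(variants: list[VariantRecord],
                       freq: FrequencyMatrix,
                       mac_min: int = 4) -> SummaryTable:
    """Tabulate variants by MAF bin, variant class and novelty; count
    singletons (MAC == 1); tabulate functional classes for variants with
    MAC >= ``mac_min``."""
    by_id = {v.id: v for v in variants}
    recs = [by_id[vid] for vid in freq.variant_ids]
    bins = maf_bin_index(freq.maf)
    cols = pd.MultiIndex.from_product([["SNP", "complex"], ["known", "novel"]])
    bc = pd.DataFrame(0, index=list(MAF_BIN_LABELS), columns=cols)
    n_single = n_novel_single = 0
    func = {k: 0 for k in FUNCTIONAL_CLASSES}
    for i, v in enumerate(recs):
        novelty = "known" if v.known else "novel"
        bc.loc[MAF_BIN_LABELS[bins[i]], (v.vclass, novelty)] += 1
        if freq.mac[i] == 1:
            n_single += 1
            if not v.known:
                n_novel_single += 1
        if freq.mac[i] >= mac_min and v.functional_class is not None:
            func[v.functional_class] += 1
    fc = pd.Series(func) if any(func.values()) else None
    return SummaryTable(bin_counts=bc, functional_counts=fc,
                        n_singletons=n_single,
                        n_novel_singletons=n_novel_single,
                        mac_threshold=mac_min)


# ---------------------------------------------------------------------------
# cross-platform concordance
# ---------------------------------------------------------------------------


def concordance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Squared Pearson correlation between two per-variant frequency
    vectors (e.g. array genotyping vs pooled sequencing)."""
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("frequency vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 variants")
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        raise ValueError("concordance undefined for zero-variance input")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
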