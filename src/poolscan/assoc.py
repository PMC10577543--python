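"""Single-variant case-control association on pooled frequency estimates.

Allele-count tables are reconstructed from rounded per-cohort dosages
(pooled data never yield integer counts directly).  The primary p-value is
a two-sided chi-square test on the 2x2 allele table, switching to the
exact conditional (hypergeometric) test when any expected cell is below 5.
Because pooled sampling inflates allele-count variance relative to
individual genotyping, a companion pool-aware p-value (two-sided rank test
on per-pool frequencies between cohorts) is reported alongside; neither is
claimed to dominate the other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .poolio import FrequencyMatrix
from .simcohort import FlagSNP, PoolDesign

log = logging.getLogger(__name__)

__all__ = [
    "AssocTable",
    "single_variant_test",
    "assoc_scan",
    "adjusted_threshold",
    "forest_table",
    "odds_ratio_ci",
    "allele_table",
]


def adjusted_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni family-wise threshold."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def allele_table(freq: FrequencyMatrix, design: PoolDesign, variant_id: str,
                 allele: str = "alt") -> tuple[int, int, int, int]:
    """2x2 allele-count table (a, b, c, d) of the designated allele:
    a = designated allele in cases, b = other allele in cases,
    c/d likewise in controls, from rounded per-cohort dosages."""
    j = freq.variant_ids.index(variant_id)
    sizes = freq.pool_sizes
    cells = []
    for cohort in ("case", "control"):
        mask = np.array([p.cohort == cohort for p in design.pools])
        f = _weighted(freq.freqs[mask, j], sizes[mask])
        n_chrom = int(2 * sizes[mask].sum())
        n_alt = int(round(f * n_chrom))
        if allele == "alt":
            cells.extend([n_alt, n_chrom - n_alt])
        elif allele == "ref":
            cells.extend([n_chrom - n_alt, n_alt])
        elif allele == "minor":
            minor_is_alt = freq.af[j] <= 0.5
            cells.extend([n_alt, n_chrom - n_alt] if minor_is_alt
                         else [n_chrom - n_alt, n_alt])
        else:
            raise ValueError("allele must be 'alt', 'ref' or 'minor'")
    return cells[0], cells[1], cells[2], cells[3]


def _weighted(freqs: np.ndarray, sizes: np.ndarray) -> float:
    ok = np.isfinite(freqs)
    w = 2.0 * sizes[ok]
    return float(np.sum(freqs[ok] * w) / np.sum(w))


def odds_ratio_ci(a: int, b: int, c: int, d: int,
                  alpha: float = 0.05) -> tuple[float, float, float]:
    """Odds ratio ad/bc with Haldane-Anscombe 0.5 correction when any cell
    is zero, and the Woolf log-OR normal-approximation CI."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell count")
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(1 - alpha / 2)
    return or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


def _chi2_p(a: int, b: int, c: int, d: int) -> tuple[float, str]:
    """Two-sided allele-table p: chi-square without continuity correction,
    or the exact conditional test when any expected cell < 5."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0:
        return 1.0, "none"
    exp = np.outer(table.sum(1), table.sum(0)) / n
    if (exp < 5).any() or (exp == 0).any():
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(min(p, 1.0)), "exact"
    chi2 = float(((table - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1)), "chi2"


def single_variant_test(freq: FrequencyMatrix, design: PoolDesign,
                        variant_id: str, allele: str = "minor",
                        mac_min: int = 4) -> dict:
    """Association row for one variant: counts, OR, CI, nominal p and the
    pool-aware rank-test p.  Variants below the MAC floor are rejected
    (pooled estimates at lower counts are dominated by read noise)."""
    j = freq.variant_ids.index(variant_id)
    if freq.mac[j] < mac_min:
        raise ValueError(f"{variant_id}: mac {freq.mac[j]} < {mac_min}")
    a, b, c, d = allele_table(freq, design, variant_id, allele)
    p_nom, method = _chi2_p(a, b, c, d)
    or_, lo, hi = odds_ratio_ci(a, b, c, d)
    case_mask = design.case_mask()
    col = freq.freqs[:, j]
    if allele == "ref" or (allele == "minor" and freq.af[j] > 0.5):
        col = 1.0 - col
    x = col[case_mask & np.isfinite(col)]
    y = col[~case_mask & np.isfinite(col)]
    if np.std(np.concatenate([x, y])) == 0:
        p_pool = 1.0
    else:
        p_pool = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return {"id": variant_id, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
            "p_nominal": p_nom, "test": method, "p_pool_aware": p_pool,
            "mac": int(freq.mac[j]), "maf": float(freq.maf[j])}


@dataclass
class AssocTable:
    """Per-variant association results with the table-level multiplicity
    context."""

    table: pd.DataFrame
    alpha: float
    n_tests: int
    adjusted_threshold: float
    skipped: list[tuple[str, str]]

    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes_adjusted"]]

    def row(self, variant_id: str) -> pd.Series:
        return self.table.set_index("id").loc[variant_id]


def assoc_scan(freq: FrequencyMatrix, design: PoolDesign,
               allele: str = "minor", mac_min: int = 4,
               alpha: float = 0.05) -> AssocTable:
    """Run the single-variant test on every variant passing the MAC floor
    and attach the Bonferroni-adjusted threshold."""
    rows = []
    skipped: list[tuple[str, str]] = []
    for vid in freq.variant_ids:
        try:
            rows.append(single_variant_test(freq, design, vid, allele, mac_min))
        except ValueError as e:
            skipped.append((vid, str(e)))
    if not rows:
        raise ValueError("no variants eligible for association testing")
    df = pd.DataFrame(rows)
    thr = adjusted_threshold(len(df), alpha)
    df["passes_adjusted"] = df["p_nominal"] <= thr
    if skipped:
        log.info("assoc: skipped %d variants below MAC %d", len(skipped), mac_min)
    return AssocTable(table=df, alpha=alpha, n_tests=len(df),
                      adjusted_threshold=thr, skipped=skipped)


def forest_table(freq: FrequencyMatrix, design: PoolDesign,
                 flags: list[FlagSNP], mac_min: int = 4) -> pd.DataFrame:
    """Per-trait odds ratios for the flagged GWAS variants, oriented to the
    designated risk allele so OR < 1 means risk-allele depletion in cases.
    Row order follows the input trait order."""
    missing = [f.id for f in flags if f.id not in freq.variant_ids]
    if missing:
        raise KeyError(f"flag variants absent from data: {missing}")
    rows = []
    for f in flags:
        res = single_variant_test(freq, design, f.id,
                                  allele=f.risk_allele, mac_min=mac_min)
        rows.append({"id": f.id, "trait": f.trait,
                     "risk_allele": f.risk_allele,
                     "odds_ratio": res["odds_ratio"],
                     "ci_low": res["ci_low"], "ci_high": res["ci_high"],
                     "p_nominal": res["p_nominal"],
                     "p_pool_aware": res["p_pool_aware"]})
    return pd.DataFrame(rows)
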