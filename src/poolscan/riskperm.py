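"""Combined risk-allele depletion statistic and its pool-label permutation
null.

The statistic is the sum over tag variants of standardized risk-allele
frequency differences between control and case pools:

    T = sum_t (mean_f_risk[control] - mean_f_risk[case]) / SE_t,

with SE_t the two-sample standard error computed from per-pool
frequencies.  Positive T means combined risk-allele depletion in cases.
The null is generated by permuting pool cohort labels (preserving the
case/control pool counts); pools, not individuals, are the exchangeable
units in pooled data.  Empirical p-values use the add-one rule, so the
smallest attainable p with n_perm permutations is 1/(n_perm+1).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .ldtags import TagSet
from .poolio import FrequencyMatrix
from .simcohort import PoolDesign

log = logging.getLogger(__name__)

__all__ = ["PermResult", "risk_frequency_matrix", "depletion_statistic",
           "permutation_test", "depletion_permutation_test"]


@dataclass
class PermResult:
    observed: float
    null_draws: int
    n_extreme: int
    p_empirical: float
    sidedness: str
    seed: int | None = None
    per_tag_z: dict[str, float] | None = None
    exhaustive: bool = False

    def to_json_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_draws": self.null_draws,
            "n_extreme": self.n_extreme,
            "p_empirical": self.p_empirical,
            "sidedness": self.sidedness,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "per_tag_z": self.per_tag_z,
        }


def risk_frequency_matrix(freq: FrequencyMatrix, tags: TagSet) -> tuple[np.ndarray, list[str]]:
    """Per-pool risk-allele frequencies for each tag (pools x tags).
    Tags with zero variance across pools are excluded with a notice."""
    if not tags.tags:
        raise ValueError("empty tag set")
    cols = []
    kept = []
    for t in tags.tags:
        risk = tags.risk_alleles.get(t)
        if risk not in ("ref", "alt"):
            raise ValueError(f"tag {t} has no designated risk allele")
        f = freq.column(t)
        f = f if risk == "alt" else 1.0 - f
        if np.nanstd(f) == 0:
            log.info("depletion statistic: excluding zero-variance tag %s", t)
            continue
        cols.append(f)
        kept.append(t)
    if not kept:
        raise ValueError("all tags excluded (zero variance)")
    return np.column_stack(cols), kept


def _statistic_from_mask(riskf: np.ndarray, case_mask: np.ndarray) -> tuple[float, np.ndarray]:
    x = riskf[~case_mask]  # controls
    y = riskf[case_mask]   # cases
    nx, ny = x.shape[0], y.shape[0]
    se = np.sqrt(x.var(axis=0, ddof=1) / nx + y.var(axis=0, ddof=1) / ny)
    se = np.where(se > 0, se, np.inf)
    z = (x.mean(axis=0) - y.mean(axis=0)) / se
    return float(z.sum()), z


def depletion_statistic(freq: FrequencyMatrix, design: PoolDesign,
                        tags: TagSet) -> tuple[float, dict[str, float]]:
    """Observed combined depletion statistic T and per-tag z values."""
    riskf, kept = risk_frequency_matrix(freq, tags)
    T, z = _statistic_from_mask(riskf, design.case_mask())
    return T, dict(zip(kept, (float(v) for v in z)))


def _statistic_many(riskf: np.ndarray, case_masks: np.ndarray) -> np.ndarray:
    """Vectorized T over many case masks (n_perm x n_pools boolean)."""
    n_case = case_masks[0].sum()
    n_ctrl = case_masks.shape[1] - n_case
    C = case_masks.astype(float)          # (P, n_pools)
    K = 1.0 - C
    s1_case = C @ riskf                   # (P, n_tags)
    s2_case = C @ riskf ** 2
    s1_ctrl = K @ riskf
    s2_ctrl = K @ riskf ** 2
    m_case = s1_case / n_case
    m_ctrl = s1_ctrl / n_ctrl
    v_case = (s2_case - n_case * m_case ** 2) / (n_case - 1)
    v_ctrl = (s2_ctrl - n_ctrl * m_ctrl ** 2) / (n_ctrl - 1)
    se = np.sqrt(np.maximum(v_case / n_case + v_ctrl / n_ctrl, 0.0))
    se = np.where(se > 0, se, np.inf)
    return ((m_ctrl - m_case) / se).sum(axis=1)


def _count_extreme(null: np.ndarray, observed: float, sidedness: str) -> int:
    tol = 1e-12 * max(1.0, abs(observed))
    if sidedness == "one_sided":
        return int(np.sum(null >= observed - tol))
    return int(np.sum(np.abs(null) >= abs(observed) - tol))


def permutation_test(statistic, freq: FrequencyMatrix, design: PoolDesign,
                     n_perm: int = 10_000, sidedness: str = "one_sided",
                     seed: int = 0, exhaustive: bool = False) -> PermResult:
    """Pool-label permutation test for any statistic of the form
    ``statistic(freq, design_labels) -> float`` where ``design_labels`` is
    a boolean case mask over pools.

    With ``exhaustive=True`` every distinct assignment of case labels to
    pools (preserving cohort pool counts) is enumerated and the p-value is
    the exact fraction of assignments at least as extreme as the observed
    one (the observed labelling is included, so p >= 1/n_total).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sidedness not in ("one_sided", "two_sided"):
        raise ValueError("sidedness must be one_sided or two_sided")
    base_mask = design.case_mask()
    n_pools = base_mask.size
    n_case = int(base_mask.sum())
    if n_case == 0 or n_case == n_pools:
        raise ValueError("both cohorts must be non-empty")
    observed = float(statistic(base_mask))

    if exhaustive:
        null = []
        for combo in itertools.combinations(range(n_pools), n_case):
            m = np.zeros(n_pools, dtype=bool)
            m[list(combo)] = True
            null.append(float(statistic(m)))
        null = np.asarray(null)
        n_total = null.size
        n_ext = _count_extreme(null, observed, sidedness)
        p = n_ext / n_total
        return PermResult(observed=observed, null_draws=n_total,
                          n_extreme=n_ext, p_empirical=p,
                          sidedness=sidedness, seed=None, exhaustive=True)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = float(statistic(rng.permutation(base_mask)))
    n_ext = _count_extreme(null, observed, sidedness)
    p = (n_ext + 1) / (n_perm + 1)
    return PermResult(observed=observed, null_draws=n_perm, n_extreme=n_ext,
                      p_empirical=p, sidedness=sidedness, seed=seed)


def depletion_permutation_test(freq: FrequencyMatrix, design: PoolDesign,
                               tags: TagSet, n_perm: int = 10_000,
                               sidedness: str = "one_sided", seed: int = 0,
                               exhaustive: bool = False) -> PermResult:
    """Permutation test for the combined depletion statistic, vectorized
    over permutations (the headline test of the analysis)."""
    riskf, kept = risk_frequency_matrix(freq, tags)
    ok = np.all(np.isfinite(riskf), axis=1)
    riskf = riskf[ok]
    base_mask = design.case_mask()[ok]
    n_pools = base_mask.size
    n_case = int(base_mask.sum())
    if n_case == 0 or n_case == n_pools:
        raise ValueError("both cohorts must be non-empty")
    observed, z = _statistic_from_mask(riskf, base_mask)

    if exhaustive:
        masks = np.zeros((math.comb(n_pools, n_case), n_pools), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n_pools), n_case)):
            masks[i, list(combo)] = True
        null = _statistic_many(riskf, masks)
        n_ext = _count_extreme(null, observed, sidedness)
        p = n_ext / null.size
        return PermResult(observed=observed, null_draws=int(null.size),
                          n_extreme=n_ext, p_empirical=p, sidedness=sidedness,
                          seed=None, per_tag_z=dict(zip(kept, map(float, z))),
                          exhaustive=True)

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n_pools), dtype=bool)
    keys = rng.random((n_perm, n_pools))
    idx = np.argpartition(keys, n_case - 1, axis=1)[:, :n_case]
    np.put_along_axis(masks, idx, True, axis=1)
    null = _statistic_many(riskf, masks)
    n_ext = _count_extreme(null, observed, sidedness)
    p = (n_ext + 1) / (n_perm + 1)
    return PermResult(observed=observed, null_draws=n_perm, n_extreme=n_ext,
                      p_empirical=p, sidedness=sidedness, seed=seed,
                      per_tag_z=dict(zip(kept, map(float, z))))
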