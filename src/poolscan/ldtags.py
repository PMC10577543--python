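"""Pool-level LD structure: correlation matrix, block clustering and
greedy tag selection.

True haplotypic r-squared is unobservable in pooled data; the Pearson
correlation of per-pool frequency estimates is used as a composite-LD
proxy.  Blocks are recovered by average-linkage hierarchical clustering on
the distance 1 - r^2, and tags are selected greedily in priority order
under a pairwise r^2 ceiling (default 0.1), each tag representing the
variants it is correlated with above the ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .poolio import FrequencyMatrix

log = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "TagSet", "pool_correlation",
           "cluster_blocks", "select_tags"]


@dataclass
class CorrelationMatrix:
    """Variant-by-variant Pearson correlation of per-pool frequencies."""

    r: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    @property
    def r2(self) -> pd.DataFrame:
        return self.r ** 2

    @property
    def variant_ids(self) -> list[str]:
        return list(self.r.index)


def pool_correlation(freq: FrequencyMatrix,
                     variant_ids: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation across pools (both cohorts combined).
    Zero-variance variants are excluded with a log notice; pools with any
    missing value are ignored pairwise via complete rows."""
    if freq.n_pools < 3:
        raise ValueError("need at least 3 pools for pool-level correlation")
    ids = variant_ids if variant_ids is not None else list(freq.variant_ids)
    cols = [freq.variant_ids.index(v) for v in ids]
    X = freq.freqs[:, cols]
    ok_rows = np.all(np.isfinite(X), axis=1)
    X = X[ok_rows]
    if X.shape[0] < 3:
        raise ValueError("fewer than 3 complete pools")
    sd = X.std(axis=0)
    keep = sd > 1e-12
    dropped = [v for v, k in zip(ids, keep) if not k]
    if dropped:
        log.info("pool_correlation: excluded %d zero-variance variants",
                 len(dropped))
    kept = [v for v, k in zip(ids, keep) if k]
    r = np.corrcoef(X[:, keep], rowvar=False)
    r = np.atleast_2d(r)
    return CorrelationMatrix(r=pd.DataFrame(r, index=kept, columns=kept),
                             dropped=dropped)


def cluster_blocks(corr: CorrelationMatrix, n_blocks: int | None = 5,
                   threshold: float | None = None) -> pd.Series:
    """Average-linkage hierarchical clustering on distance 1 - r^2, cut to
    ``n_blocks`` clusters (or at a distance ``threshold``).  Genomic
    contiguity is not enforced."""
    ids = corr.variant_ids
    n = len(ids)
    if n_blocks is not None and n_blocks > n:
        raise ValueError(f"n_blocks {n_blocks} exceeds {n} variants")
    d = 1.0 - corr.r2.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 1.0)
    Z = average(squareform(d, checks=False))
    if threshold is not None:
        labels = fcluster(Z, t=threshold, criterion="distance")
    else:
        labels = fcluster(Z, t=n_blocks, criterion="maxclust")
    return pd.Series(labels, index=ids, name="block")


@dataclass
class TagSet:
    """Greedily selected quasi-independent tag variants."""

    tags: list[str]
    r2_max: float
    representatives: dict[str, list[str]]
    risk_alleles: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tags)


def select_tags(corr: CorrelationMatrix,
                candidates: list[tuple[str, float]],
                r2_max: float = 0.1,
                positions: dict[str, int] | None = None) -> TagSet:
    """Greedy tag selection at an r^2 ceiling.

    ``candidates`` are (variant id, priority) pairs; higher priority is
    visited first (ties broken by genomic position when given, then id).
    A candidate becomes a tag iff its max r^2 with the already-kept tags
    is <= ``r2_max``.  Each tag's representatives are the candidates with
    r^2 above the ceiling to that tag.  The pairwise-r^2 postcondition is
    asserted on every output.
    """
    ids = set(corr.variant_ids)
    unknown = [c for c, _ in candidates if c not in ids]
    if unknown:
        raise KeyError(f"candidates absent from correlation matrix: {unknown}")
    r2 = corr.r2

    def sort_key(item: tuple[str, float]):
        vid, prio = item
        pos = positions.get(vid, 0) if positions else 0
        return (-prio, pos, vid)

    ordered = sorted(candidates, key=sort_key)
    tags: list[str] = []
    reps: dict[str, list[str]] = {}
    for vid, _ in ordered:
        if tags and float(r2.loc[vid, tags].max()) > r2_max:
            continue
        tags.append(vid)
        reps[vid] = []
    for vid, _ in ordered:
        if vid in reps:
            continue
        for t in tags:
            if float(r2.loc[vid, t]) > r2_max:
                reps[t].append(vid)
    for i, t in enumerate(tags):
        for u in tags[:i]:
            assert float(r2.loc[t, u]) <= r2_max + 1e-12, \
                "tag set violates pairwise r2 ceiling"
    return TagSet(tags=tags, r2_max=r2_max, representatives=reps)
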