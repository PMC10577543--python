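"""Variance-component kernel association (SKAT-style) and directional
weighted burden tests on pooled dosages.

Individual genotypes do not exist in pooled data, so pools are the test
units: the "genotype" of pool p at variant v is the expected alternate
allele count 2 * pool_size * f_hat[p, v], and the response is the pool's
cohort label.  The kernel score statistic is

    Q = (y - mu)' G W^2 G' (y - mu)

with W = diag(w_v), w_v the Beta(1, 25) density evaluated at the variant's
MAF (the conventional up-weighting of rarer variants), and mu the fitted
null mean (intercept-only by default, i.e. the case-pool fraction).  Under
the null, Q follows a mixture of chi-square(1) variables whose weights are
the eigenvalues of the null-projected kernel; the tail probability is
computed by moment matching (mean, variance and kurtosis matched to a
scaled noncentral chi-square), with a Monte-Carlo quadratic-form sampler
as fallback and cross-check.

The directional burden test collapses weighted minor-allele dosages into
one score per pool and compares cohorts by a standardized difference with
a pool-label permutation p-value; its sign reports depletion (negative)
versus enrichment of minor alleles in case pools.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .poolio import FrequencyMatrix
from .simcohort import PoolDesign, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "KernelTestResult", "beta_maf_weights", "build_dosage_matrix",
    "mixture_chisq_sf", "monte_carlo_mixture_sf", "skat_test", "burden_test",
    "load_regions_bed", "region_variants", "region_scan",
]


@dataclass
class KernelTestResult:
    Q: float
    p_value: float
    eigenvalues: np.ndarray
    method: str  # "moment_matching" or "monte_carlo"
    region: str | None = None
    n_variants: int = 0
    weights_spec: str = "beta(1,25)"

    def to_json_dict(self) -> dict:
        return {"Q": self.Q, "p_value": self.p_value,
                "eigenvalues": [float(x) for x in self.eigenvalues],
                "method": self.method, "region": self.region,
                "n_variants": self.n_variants,
                "weights_spec": self.weights_spec}


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density evaluated at each variant's MAF — the standard
    kernel-test weighting that emphasises rarer variants."""
    maf = np.clip(np.asarray(maf, dtype=float), 1e-6, 1 - 1e-6)
    return stats.beta.pdf(maf, a, b)


def build_dosage_matrix(freq: FrequencyMatrix, design: PoolDesign,
                        variant_ids: list[str], orient: str = "minor",
                        ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Expected per-pool allele dosages for a set of variants.

    G[p, v] = 2 * pool_size_p * f_hat[p, v] with f oriented to the minor
    (default) or alternate allele; y[p] = 1 for case pools.  Pools with a
    missing estimate contribute dosage via the combined frequency (mean
    imputation) — rare with the default QC rule."""
    if not variant_ids:
        raise ValueError("empty variant set")
    cols = [freq.variant_ids.index(v) for v in variant_ids]
    F = freq.freqs[:, cols].copy()
    af = freq.af[cols]
    fill = np.broadcast_to(af, F.shape)
    F = np.where(np.isfinite(F), F, fill)
    if orient == "minor":
        flip = af > 0.5
        F[:, flip] = 1.0 - F[:, flip]
    elif orient != "alt":
        raise ValueError("orient must be 'minor' or 'alt'")
    G = 2.0 * freq.pool_sizes[:, None] * F
    y = design.case_mask().astype(float)
    return G, y, list(variant_ids)


# ---------------------------------------------------------------------------
# p-values for quadratic forms
# ---------------------------------------------------------------------------


def mixture_chisq_sf(q: float, eigenvalues: np.ndarray) -> float:
    """Tail probability P(sum_i lambda_i chi2_1 >= q) by moment matching:
    the mixture's mean, variance and kurtosis are matched to a scaled
    noncentral chi-square.  Exact when all eigenvalues are equal."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    c1 = lam.sum()
    c2 = (lam ** 2).sum()
    c3 = (lam ** 3).sum()
    c4 = (lam ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = math.sqrt(2 * (df + 2 * delta))
    t = (q - c1) / math.sqrt(2 * c2)
    x = t * sigma_x + mu_x
    p = float(stats.ncx2.sf(x, df, delta)) if delta > 0 else float(stats.chi2.sf(x, df))
    return min(max(p, 1e-300), 1.0)


def monte_carlo_mixture_sf(q: float, eigenvalues: np.ndarray,
                           n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo tail probability of the chi-square mixture with the
    add-one rule (never returns 0)."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    rng = np.random.default_rng(seed)
    draws = (lam[None, :] * rng.chisquare(1.0, size=(n_draws, lam.size))).sum(axis=1)
    return (int(np.sum(draws >= q)) + 1) / (n_draws + 1)


def _null_model(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Fitted null mean and design matrix of the logistic null model."""
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
        mu = np.full(n, y.mean())
    else:
        import statsmodels.api as sm

        X = sm.add_constant(np.asarray(covariates, dtype=float))
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        mu = np.asarray(fit.fittedvalues)
    return mu, X


def skat_test(G: np.ndarray, y: np.ndarray, weights: np.ndarray,
              covariates: np.ndarray | None = None,
              region: str | None = None,
              method: str = "moment_matching",
              mc_draws: int = 200_000, seed: int = 0,
              eig_rtol: float = 1e-8) -> KernelTestResult:
    """Variance-component kernel score test of pool dosages against the
    cohort label.

    Eigenvalues below ``eig_rtol`` times the largest are dropped for
    numerical stability.  If the eigendecomposition fails, or
    ``method='monte_carlo'``, the p-value comes from the Monte-Carlo
    quadratic-form sampler instead of moment matching.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if G.shape[0] != y.size or G.shape[1] != w.size:
        raise ValueError("G/y/weights shape mismatch")
    if np.unique(y).size < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 pools per class")
    mu, X = _null_model(y, covariates)
    resid = y - mu
    GW = G * w[None, :]
    Q = float(resid @ (GW @ (GW.T @ resid)))
    v = mu * (1 - mu)
    # null projection: P0 = V - V X (X'VX)^-1 X'V ; eigenvalues of
    # P0^{1/2} K P0^{1/2} equal those of (GW)' P0 (GW)
    XtVX = X.T @ (v[:, None] * X)
    VX = v[:, None] * X
    P0GW = v[:, None] * GW - VX @ np.linalg.solve(XtVX, VX.T @ GW)
    M = GW.T @ P0GW
    used_mc = method == "monte_carlo"
    try:
        lam = np.linalg.eigvalsh((M + M.T) / 2)
    except np.linalg.LinAlgError:
        log.warning("eigendecomposition failed; falling back to Monte Carlo")
        lam = None
        used_mc = True
    if lam is not None:
        lam = lam[lam > eig_rtol * max(lam.max(), 1e-300)]
        if lam.size == 0:
            return KernelTestResult(Q=Q, p_value=1.0, eigenvalues=np.array([]),
                                    method="degenerate", region=region,
                                    n_variants=G.shape[1])
    if used_mc and lam is None:
        # estimate eigenvalues is impossible; sample Q under permuted labels
        raise RuntimeError("kernel eigendecomposition failed irrecoverably")
    if used_mc:
        p = monte_carlo_mixture_sf(Q, lam, n_draws=mc_draws, seed=seed)
        meth = "monte_carlo"
    else:
        p = mixture_chisq_sf(Q, lam)
        meth = "moment_matching"
    return KernelTestResult(Q=Q, p_value=max(min(p, 1.0), 0.0), eigenvalues=lam,
                            method=meth, region=region, n_variants=G.shape[1])


@dataclass
class BurdenResult:
    z: float
    sign: int
    p_value: float
    n_perm: int
    region: str | None = None
    n_variants: int = 0
    exhaustive: bool = False


def burden_test(G: np.ndarray, y: np.ndarray, weights: np.ndarray,
                n_perm: int = 10_000, seed: int = 0,
                region: str | None = None,
                exhaustive: bool = False) -> BurdenResult:
    """Directional weighted burden test: collapse B = G w per pool and
    compare cohorts with a two-sided label-permutation test on the
    standardized mean difference.  sign < 0 means minor-allele depletion
    in case pools."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    B = G @ w
    case = y == 1
    n_case, n_ctrl = int(case.sum()), int((~case).sum())
    if min(n_case, n_ctrl) < 2:
        raise ValueError("need >= 2 pools per class")
    if np.std(B) == 0:
        import warnings

        warnings.warn("zero-variance burden; p = 1", stacklevel=2)
        return BurdenResult(z=0.0, sign=0, p_value=1.0, n_perm=0,
                            region=region, n_variants=G.shape[1])

    def zstat(mask: np.ndarray) -> float:
        x, c = B[mask], B[~mask]
        se = math.sqrt(x.var(ddof=1) / x.size + c.var(ddof=1) / c.size)
        return (x.mean() - c.mean()) / se if se > 0 else 0.0

    z_obs = zstat(case)
    tol = 1e-12 * max(1.0, abs(z_obs))
    if exhaustive:
        n = y.size
        null = []
        for combo in itertools.combinations(range(n), n_case):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            null.append(zstat(m))
        null = np.asarray(null)
        n_ext = int(np.sum(np.abs(null) >= abs(z_obs) - tol))
        p = n_ext / null.size
        return BurdenResult(z=float(z_obs), sign=int(np.sign(z_obs)),
                            p_value=p, n_perm=int(null.size), region=region,
                            n_variants=G.shape[1], exhaustive=True)
    rng = np.random.default_rng(seed)
    n_ext = 0
    for _ in range(n_perm):
        if abs(zstat(rng.permutation(case))) >= abs(z_obs) - tol:
            n_ext += 1
    p = (n_ext + 1) / (n_perm + 1)
    return BurdenResult(z=float(z_obs), sign=int(np.sign(z_obs)), p_value=p,
                        n_perm=n_perm, region=region, n_variants=G.shape[1])


# ---------------------------------------------------------------------------
# region handling
# ---------------------------------------------------------------------------


def load_regions_bed(path: str) -> list[tuple[str, int, int]]:
    """Named intervals from a BED file (0-based half-open; 4th column is
    the region name).  Duplicate names are rejected."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate region names: {dup}")
    return [(str(r["name"]), int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]


def region_variants(regions: list[tuple[str, int, int]],
                    variants: list[VariantRecord],
                    eligible_ids: set[str] | None = None) -> dict[str, list[str]]:
    """Map region name -> member variant ids by position (a variant may
    belong to several regions)."""
    out: dict[str, list[str]] = {}
    for name, s, e in regions:
        members = [v.id for v in variants if s <= v.position < e
                   and (eligible_ids is None or v.id in eligible_ids)]
        out[name] = members
    return out


def region_scan(freq: FrequencyMatrix, design: PoolDesign,
                regions: dict[str, list[str]],
                tests: tuple[str, ...] = ("skat", "burden"),
                mac_min: int = 4, weights_beta: tuple[float, float] = (1.0, 25.0),
                n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Run the selected tests per region, one row per region x test.
    P-values are reported raw (no multiplicity correction).  Regions left
    empty after the MAC filter get an explicit no-test row."""
    if not regions:
        raise ValueError("no regions given")
    eligible = {v for v, m in zip(freq.variant_ids, freq.mac) if m >= mac_min}
    if all(not [v for v in ids if v in eligible] for ids in regions.values()):
        raise ValueError("all regions empty after MAC filter")
    rows = []
    for k, (name, ids) in enumerate(regions.items()):
        ids = [v for v in ids if v in eligible]
        if not ids:
            for t in tests:
                rows.append({"region": name, "test": t, "n_variants": 0,
                             "statistic": np.nan, "p": np.nan,
                             "method": "no_test"})
            continue
        G, y, _ = build_dosage_matrix(freq, design, ids, orient="minor")
        maf = freq.maf[[freq.variant_ids.index(v) for v in ids]]
        w = beta_maf_weights(maf, *weights_beta)
        for t in tests:
            if t == "skat":
                res = skat_test(G, y, w, region=name, seed=seed + k)
                rows.append({"region": name, "test": "skat",
                             "n_variants": len(ids), "statistic": res.Q,
                             "p": res.p_value, "method": res.method})
            elif t == "burden":
                res = burden_test(G, y, w, n_perm=n_perm, seed=seed + k,
                                  region=name)
                rows.append({"region": name, "test": "burden",
                             "n_variants": len(ids), "statistic": res.z,
                             "p": res.p_value, "method": "permutation",
                             "sign": res.sign})
            else:
                raise ValueError(f"unknown test {t}")
    return pd.DataFrame(rows)
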