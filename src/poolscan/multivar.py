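"""Multivariate structure of pool frequency profiles.

PCA of the pools-by-variants frequency matrix exposes cohort-correlated
genotype profiles: a component dominated by a group of linked
low-frequency variants separates pools by how many carriers of the
underlying haplotype they contain.  Components are screened for cohort
separation with a two-sided Mann-Whitney rank test (Bonferroni-adjusted
across the screened components), classification of pools from selected
component scores is validated by a label-permutation test, and feature
importance is read off PC loadings and tree-ensemble permutation
importance.  Correlating high-importance variants' minor-allele
frequencies with the flag variants' risk-allele frequencies reveals
whether a profile rides a risk or a non-risk background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.svm import SVC

from .poolio import FrequencyMatrix
from .simcohort import FlagSNP, PoolDesign

log = logging.getLogger(__name__)

__all__ = [
    "PCAResult", "ClassifierResult", "SeparationPattern", "pca_pools",
    "pc_cohort_test", "screen_components", "classify_pools",
    "find_separating_components", "pc_feature_importance",
    "tree_importance", "importance_risk_correlation",
]


@dataclass
class PCAResult:
    """Scores, orthonormal loadings and explained-variance fractions of a
    pool-profile PCA.  Component signs are fixed deterministically by
    forcing each component's largest-magnitude loading positive."""

    scores: np.ndarray        # (n_pools, k)
    loadings: np.ndarray      # (n_variants, k), orthonormal columns
    var_explained: np.ndarray  # (k,)
    pool_ids: list[str]
    variant_ids: list[str]
    column_means: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def score(self, component: int) -> np.ndarray:
        """Scores of one component (1-based)."""
        return self.scores[:, component - 1]

    def loading(self, component: int) -> pd.Series:
        return pd.Series(self.loadings[:, component - 1],
                         index=self.variant_ids)


def pca_pools(freq: FrequencyMatrix, mac_min: int = 4, center: bool = True,
              scale: bool = False, n_components: int | None = None) -> PCAResult:
    """PCA of the pools x variants frequency matrix.

    Variants below the MAC floor or with any missing pool are excluded;
    frequencies are centered (and optionally unit-scaled) per variant.
    Equivalent to the eigendecomposition of the pool-wise covariance
    matrix, computed by SVD.
    """
    if freq.n_pools < 3:
        raise ValueError("need at least 3 pools")
    keep = (freq.mac >= mac_min) & np.all(np.isfinite(freq.freqs), axis=0)
    ids = [v for v, k in zip(freq.variant_ids, keep) if k]
    X = freq.freqs[:, keep].astype(float)
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 variants retained for PCA")
    mu = X.mean(axis=0)
    Xc = X - mu if center else X.copy()
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    kmax = min(X.shape[0] - 1 if center else X.shape[0], X.shape[1])
    k = kmax if n_components is None else n_components
    if k > kmax:
        raise ValueError(f"requested {k} components, at most {kmax} available")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    total_var = (Xc ** 2).sum()
    var_explained = (s ** 2) / total_var if total_var > 0 else np.zeros(k)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    return PCAResult(scores=U * s, loadings=Vt.T, var_explained=var_explained,
                     pool_ids=list(freq.pool_ids), variant_ids=ids,
                     column_means=mu)


def pc_cohort_test(pca: PCAResult | np.ndarray, design: PoolDesign,
                   component: int = 1) -> float:
    """Two-sided Mann-Whitney rank-test p for cohort separation along one
    component: exact when both cohorts have <= 25 pools and there are no
    ties, normal approximation with tie correction otherwise."""
    scores = pca.score(component) if isinstance(pca, PCAResult) else np.asarray(pca)
    mask = design.case_mask()
    x, y = scores[mask], scores[~mask]
    if x.size < 2 or y.size < 2:
        raise ValueError("both cohorts need >= 2 pools")
    if np.std(scores) == 0:
        warnings.warn("constant component scores; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(scores).size < scores.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def screen_components(pca: PCAResult, design: PoolDesign,
                      n_components: int = 3, alpha: float = 0.05,
                      adjust: str = "bonferroni") -> pd.DataFrame:
    """Rank-test each of the first ``n_components`` components for cohort
    separation.  Because several components are screened, significance is
    declared at the Bonferroni-adjusted level alpha/n by default
    (``adjust='none'`` for raw alpha)."""
    n = min(n_components, pca.k)
    thr = alpha / n if adjust == "bonferroni" else alpha
    rows = []
    for c in range(1, n + 1):
        p = pc_cohort_test(pca, design, c)
        rows.append({"component": c, "p": p, "significant": p <= thr,
                     "var_explained": float(pca.var_explained[c - 1])})
    return pd.DataFrame(rows)


@dataclass
class ClassifierResult:
    accuracy: float
    p_perm: float
    n_perm: int
    seed: int
    components: tuple[int, ...]

    def to_json_dict(self) -> dict:
        return {"accuracy": self.accuracy, "p_perm": self.p_perm,
                "n_perm": self.n_perm, "seed": self.seed,
                "components": list(self.components)}


def _loo_accuracy(X: np.ndarray, y: np.ndarray, C: float) -> float:
    n = y.size
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return correct / n


def classify_pools(pca: PCAResult, design: PoolDesign,
                   components: tuple[int, ...] = (2, 3),
                   n_perm: int = 1000, seed: int = 0,
                   C: float = 1.0) -> ClassifierResult:
    """Linear maximum-margin classification of pools from selected
    component scores, with leave-one-pool-out accuracy and a
    label-permutation p-value (classifier refit for every permutation)."""
    y = design.case_mask().astype(int)
    if np.unique(y).size < 2:
        raise ValueError("need both cohorts to classify")
    X = np.column_stack([pca.score(c) for c in components])
    acc = _loo_accuracy(X, y, C)
    rng = np.random.default_rng(seed)
    n_ext = 0
    for _ in range(n_perm):
        acc_p = _loo_accuracy(X, rng.permutation(y), C)
        if acc_p >= acc - 1e-12:
            n_ext += 1
    p = (n_ext + 1) / (n_perm + 1)
    return ClassifierResult(accuracy=acc, p_perm=p, n_perm=n_perm, seed=seed,
                            components=tuple(components))


@dataclass
class SeparationPattern:
    """Outcome of the risk/protective profile search: the component pair,
    their rank-test p-values, mean risk-allele correlations of their
    high-importance sets, and the permutation-validated classification of
    pools from the pair."""

    found: bool
    positive_pc: int | None = None
    negative_pc: int | None = None
    p_positive: float | None = None
    p_negative: float | None = None
    corr_positive: float | None = None
    corr_negative: float | None = None
    classifier: "ClassifierResult | None" = None


def find_separating_components(pca: PCAResult, freq: FrequencyMatrix,
                               design: PoolDesign, flags: list[FlagSNP],
                               n_components: int = 5,
                               min_corr: float = 0.1, alpha: float = 0.05,
                               n_perm: int = 199, seed: int = 0,
                               ) -> SeparationPattern:
    """Search the leading components for the two-profile risk pattern.

    Each of the top ``n_components`` components is first oriented so its
    score rises with the aggregate minor-allele content of low-frequency
    variants (a linked group of n variants contributes loading mass of
    order sqrt(n), so the dominant group sets the direction), then
    summarised by the mean Pearson correlation, across pools, between the
    oriented score and the flag variants' risk-allele frequencies.  The
    candidate risk-linked profile is the component with
    the largest positive mean correlation and the protective-linked
    profile the one with the most negative; both must exceed ``min_corr``
    in magnitude.  Because this selection never looks at cohort labels,
    the subsequent permutation-validated linear classification of pools
    from the selected component pair is an unbiased significance gate:
    the pattern is declared found when the pair separates cohorts at
    ``alpha``.  Per-component rank-test p-values are reported for
    inspection but are deliberately not a gate — a single component's
    rank test can be marginal even when the two profiles jointly
    distinguish the cohorts clearly.
    """
    n = min(n_components, pca.k)
    flag_cols = []
    for f in flags:
        col = freq.column(f.id)
        flag_cols.append(col if f.risk_allele == "alt" else 1.0 - col)
    F = np.column_stack(flag_cols)
    # minor-allele orientation of loadings: a positive oriented loading
    # means the component score rises with the variant's minor allele
    af = np.array([freq.af[freq.variant_ids.index(v)]
                   for v in pca.variant_ids])
    orient = np.where(af <= 0.5, 1.0, -1.0)
    lowfreq = np.minimum(af, 1 - af) < 0.05
    cand: list[tuple[int, float, float]] = []
    for c in range(1, n + 1):
        load = pca.loadings[:, c - 1] * orient
        # orient the component along its aggregate low-frequency
        # minor-allele direction: a linked group of n variants contributes
        # loading mass ~ sqrt(n), so the dominant group sets the sign
        sgn = 1.0 if load[lowfreq].sum() >= 0 else -1.0
        s = sgn * pca.score(c)
        ok = np.all(np.isfinite(F), axis=1) & np.isfinite(s)
        corr = float(np.mean([np.corrcoef(s[ok], F[ok, j])[0, 1]
                              for j in range(F.shape[1])]))
        cand.append((c, corr, pc_cohort_test(pca, design, c)))
    cpos, rpos, ppos = max(cand, key=lambda t: t[1])
    cneg, rneg, pneg = min(cand, key=lambda t: t[1])
    if rpos < min_corr or rneg > -min_corr or cpos == cneg:
        return SeparationPattern(found=False)
    clf = classify_pools(pca, design, components=(cpos, cneg),
                         n_perm=n_perm, seed=seed)
    return SeparationPattern(found=clf.p_perm < alpha,
                             positive_pc=cpos, negative_pc=cneg,
                             p_positive=ppos, p_negative=pneg,
                             corr_positive=rpos, corr_negative=rneg,
                             classifier=clf)


def pc_feature_importance(pca: PCAResult, component: int,
                          top_k: int = 20) -> pd.DataFrame:
    """Per-variant importance |loading| for one component, with the top_k
    selection (ties broken by input order, i.e. genomic position)."""
    if component > pca.k:
        raise ValueError(f"component {component} > k={pca.k}")
    imp = np.abs(pca.loadings[:, component - 1])
    if top_k > imp.size:
        warnings.warn(f"top_k {top_k} exceeds {imp.size} variants; capped",
                      stacklevel=2)
        top_k = imp.size
    order = np.argsort(-imp, kind="stable")
    df = pd.DataFrame({"id": [pca.variant_ids[i] for i in order],
                       "importance": imp[order],
                       "loading": pca.loadings[order, component - 1]})
    df["selected"] = False
    df.iloc[:top_k, df.columns.get_loc("selected")] = True
    df.attrs["component"] = component
    return df


def tree_importance(freq: FrequencyMatrix, design: PoolDesign,
                    mac_min: int = 4, n_trees: int = 500, n_seeds: int = 5,
                    seed: int = 0, method: str = "random_forest",
                    n_repeats: int = 5) -> pd.DataFrame:
    """Tree-ensemble feature importance for cohort classification from
    pool frequencies, robust to multicollinearity among linked variants.

    Importance is permutation importance (mean accuracy drop when one
    variant's column is shuffled), averaged over ``n_seeds`` refits, then
    clipped at zero and normalized to sum to one."""
    y = design.case_mask().astype(int)
    if np.unique(y).size < 2:
        raise ValueError("need both cohorts")
    keep = (freq.mac >= mac_min) & np.all(np.isfinite(freq.freqs), axis=0)
    ids = [v for v, k in zip(freq.variant_ids, keep) if k]
    X = freq.freqs[:, keep]
    acc = np.zeros(X.shape[1])
    for s in range(n_seeds):
        if method == "random_forest":
            clf = RandomForestClassifier(n_estimators=n_trees,
                                         random_state=seed + s)
        elif method == "boosting":
            clf = GradientBoostingClassifier(n_estimators=min(n_trees, 200),
                                             random_state=seed + s)
        else:
            raise ValueError("method must be random_forest or boosting")
        clf.fit(X, y)
        pi = permutation_importance(clf, X, y, n_repeats=n_repeats,
                                    random_state=seed + s)
        acc += pi.importances_mean
    acc /= n_seeds
    clipped = np.clip(acc, 0.0, None)
    total = clipped.sum()
    norm = clipped / total if total > 0 else clipped
    df = pd.DataFrame({"id": ids, "importance_raw": acc, "importance": norm})
    return df.sort_values("importance", ascending=False,
                          kind="stable").reset_index(drop=True)


def importance_risk_correlation(freq: FrequencyMatrix,
                                important_sets: dict[str, list[str]],
                                flags: list[FlagSNP]) -> pd.DataFrame:
    """Pearson correlation, across pools, between each high-importance
    variant's minor-allele frequency and each flag variant's risk-allele
    frequency.  Positive entries mean the minor allele co-occurs with the
    risk allele.  Rows carry a ``set`` column naming the importance set."""
    if not important_sets or all(not v for v in important_sets.values()):
        raise ValueError("importance sets are empty")
    missing = [f.id for f in flags if f.id not in freq.variant_ids]
    if missing:
        raise KeyError(f"flags absent from data: {missing}")
    flag_cols = {}
    for f in flags:
        col = freq.column(f.id)
        flag_cols[f.id] = col if f.risk_allele == "alt" else 1.0 - col
    rows = []
    for set_name, ids in important_sets.items():
        for vid in ids:
            j = freq.variant_ids.index(vid)
            col = freq.freqs[:, j]
            if freq.af[j] > 0.5:
                col = 1.0 - col
            if np.nanstd(col) == 0:
                log.info("importance correlation: %s has zero variance", vid)
                continue
            row = {"set": set_name, "id": vid}
            for f in flags:
                fc = flag_cols[f.id]
                ok = np.isfinite(col) & np.isfinite(fc)
                if np.std(fc[ok]) == 0:
                    row[f.id] = np.nan
                else:
                    row[f.id] = float(np.corrcoef(col[ok], fc[ok])[0, 1])
            rows.append(row)
    return pd.DataFrame(rows)
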