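"""Supervised SNP-set association analysis.

For a SNP set S the procedure is:

1. screen each SNP by the Wald p-value of a univariate logistic regression of
   the trait on its genotype;
2. form v (default 20) nested candidate subsets by thresholding at each
   increment of 100/v percentiles of the screening p-values;
3. extract the first PC of each unique candidate subset (categorical PCA,
   standard PCA, or logistic PCA), regress the trait on it, and keep the
   signed t statistic of largest magnitude as the set's M statistic;
4. build a null sample of M by redrawing trait labels from
   Bernoulli(prevalence) and repeating steps 1-3;
5. report the add-one empirical p-value, with Benjamini-Hochberg adjustment
   across sets.

Because the M statistic maximizes over subsets chosen with the trait, its
null distribution is not any standard law; the permutation null reproduces
the whole selection procedure.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .baselines import binarize_genotypes, fit_lpca_scores, fit_pca_scores
from .cpca import FitConfig, _fit_l1_fast, first_pc_scores, fit_cpca
from .glm import logistic_wald, per_snp_pvalues, wald_t_fast
from .setio import GenotypeMatrix, Phenotype, SnpSet

__all__ = [
    "CandidateSubsets",
    "AssociationResult",
    "candidate_subsets",
    "subset_t",
    "m_statistic",
    "permutation_null",
    "empirical_pvalue",
    "bh_adjust",
    "run_snpset_analysis",
    "results_frame",
]

Method = Literal["cpca", "pca", "lpca"]


@dataclass
class CandidateSubsets:
    """Nested candidate SNP subsets from percentile thresholds on p-values."""

    subsets: list[np.ndarray]  # local column indices, nested
    thresholds: np.ndarray
    v: int

    def unique(self) -> list[np.ndarray]:
        """Distinct subsets in increasing size order (duplicates collapsed)."""
        seen: set[tuple] = set()
        out = []
        for s in self.subsets:
            key = tuple(s.tolist())
            if key not in seen:
                seen.add(key)
                out.append(s)
        return out


@dataclass
class LogisticFit:
    """Wald summary for the trait-on-score logistic regression."""

    beta1: float
    se1: float
    t: float
    converged: bool


@dataclass
class AssociationResult:
    set_id: str
    n_snps: int
    M: float
    optimal_subset: np.ndarray  # global SNP indices
    null_M: np.ndarray
    p_value: float
    p_adjusted: float = np.nan

    @property
    def n_permutations(self) -> int:
        return int(self.null_M.size)


def candidate_subsets(pvalues: np.ndarray, v: int = 20) -> CandidateSubsets:
    """Nested subsets at nearest-rank percentiles 100/v, 200/v, ..., 100.

    Threshold w is the nearest-rank (w * 100/v)-th percentile of the
    screening p-values; subset w holds every SNP with p <= threshold, so
    subset 1 is never empty and subset v is the full set.
    """
    p = np.asarray(pvalues, dtype=float)
    d = p.size
    if d == 0:
        raise ValueError("need at least one SNP")
    order = np.sort(p)
    subsets = []
    thresholds = np.empty(v)
    for w in range(1, v + 1):
        rank = int(np.ceil(w * d / v))
        T = order[rank - 1]
        thresholds[w - 1] = T
        subsets.append(np.flatnonzero(p <= T))
    return CandidateSubsets(subsets=subsets, thresholds=thresholds, v=v)


def _scores_for(
    values: np.ndarray, method: Method, config: FitConfig, fit_seed: int
) -> np.ndarray:
    if method == "pca":
        return fit_pca_scores(values).scores
    cfg = FitConfig(
        latent_dim=1,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
        n_restarts=config.n_restarts,
        seed=fit_seed,
        damping=config.damping,
        ridge=config.ridge,
    )
    if method == "cpca":
        return first_pc_scores(fit_cpca(values, cfg))
    if method == "lpca":
        return fit_lpca_scores(values, cfg).scores
    raise ValueError(f"unknown method {method!r}")


class _ScoreCache:
    """First-PC scores keyed by SNP-index tuple, with warm starts.

    The PC extractors are unsupervised, so scores depend on the genotype
    submatrix only — across permutation rounds the same subsets recur and
    their fits are reused.  For the exponential-family fits the cache also
    keeps the fitted parameters: a missing subset is fitted warm-started
    from its nested parent (scores copied; parent columns' loadings and
    offsets copied, new columns started at zero loading and empirical
    log-odds), which typically converges in a handful of iterations.
    """

    def __init__(self, values: np.ndarray, method: Method, config: FitConfig, seed: int):
        self.method = method
        self.config = config
        self.seed = seed
        if method == "lpca":
            self.codes = binarize_genotypes(values)
            self.c = 2
        else:
            self.codes = values
            self.c = 3
        self.values = values
        self._scores: dict[tuple, np.ndarray] = {}
        self._params: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _warm_init(self, local_idx: np.ndarray, parent_key: tuple | None):
        if parent_key is None or parent_key not in self._params:
            return None
        pU, pV, pmu = self._params[parent_key]
        pos = {snp: c for c, snp in enumerate(parent_key)}
        K = self.c - 1
        d = local_idx.size
        V0 = np.zeros((K, d, 1))
        mu0 = np.zeros((K, d))
        for c_new, snp in enumerate(local_idx):
            c_old = pos.get(int(snp))
            if c_old is not None:
                V0[:, c_new, 0] = pV[:, c_old, 0]
                mu0[:, c_new] = pmu[:, c_old]
            else:
                col = self.codes[:, snp]
                n0 = float((col == 0).sum())
                for k in range(K):
                    nk = float((col == k + 1).sum())
                    mu0[k, c_new] = np.log((nk + 0.5) / (n0 + 0.5))
        return pU.copy(), V0, mu0

    def scores(self, local_idx: np.ndarray, parent_key: tuple | None = None) -> np.ndarray:
        key = tuple(int(i) for i in local_idx)
        hit = self._scores.get(key)
        if hit is not None:
            return hit
        if self.method == "pca":
            hit = fit_pca_scores(self.values[:, local_idx]).scores
        elif (self.c - 1) * local_idx.size <= 1:
            # a single binary SNP admits no latent factor below saturation;
            # its own coding is the unique 1-d ordering of the samples
            hit = self.codes[:, local_idx[0]].astype(float)
        else:
            init = self._warm_init(local_idx, parent_key)
            cfg = FitConfig(
                latent_dim=1,
                max_iterations=self.config.max_iterations,
                tolerance=self.config.tolerance,
                n_restarts=self.config.n_restarts,
                seed=(self.seed + zlib.crc32(np.asarray(key, dtype=np.int64).tobytes()))
                % (2**31),
                damping=self.config.damping,
                ridge=self.config.ridge,
            )
            U, V, mu = _fit_l1_fast(
                np.ascontiguousarray(self.codes[:, local_idx]), self.c, cfg, init
            )
            self._params[key] = (U, V, mu)
            hit = U[:, 0].copy()
        self._scores[key] = hit
        return hit


def _pipeline_config(config: FitConfig | None) -> FitConfig:
    if config is not None:
        return config
    # leaner solver settings for the permutation pipeline: one start with a
    # looser tolerance suffices, and a small natural-parameter ridge keeps
    # the optimum finite (separated samples would otherwise get unbounded
    # scores that dominate the downstream logistic regression)
    return FitConfig(
        latent_dim=1, max_iterations=40, tolerance=1e-3, n_restarts=1, seed=0,
        ridge=1e-3,
    )


def subset_t(
    subset: SnpSet | np.ndarray,
    G: GenotypeMatrix | np.ndarray,
    y: Phenotype | np.ndarray,
    method: Method = "cpca",
    config: FitConfig | None = None,
) -> float:
    """Wald t of the trait regressed on the subset's first-PC scores."""
    idx = subset.snp_indices if isinstance(subset, SnpSet) else np.asarray(subset)
    if idx.size == 0:
        raise ValueError("subset must be non-empty")
    values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    yv = y.y if isinstance(y, Phenotype) else np.asarray(y)
    config = _pipeline_config(config)
    cache = _ScoreCache(values, method, config, config.seed)
    scores = cache.scores(idx)
    _, _, t, _ = logistic_wald(scores, yv)
    return float(t)


def _m_from_cache(
    cache: _ScoreCache, yv: np.ndarray, v: int
) -> tuple[float, np.ndarray]:
    pvals = per_snp_pvalues(cache.values, yv)
    cands = candidate_subsets(pvals, v=v)
    best_t = 0.0
    best_abs = -np.inf
    best_subset = cands.subsets[0]
    parent: tuple | None = None
    for local in cands.unique():  # increasing size: ties favor parsimony
        scores = cache.scores(local, parent_key=parent)
        parent = tuple(int(i) for i in local)
        t = wald_t_fast(scores, yv)
        if abs(t) > best_abs:
            best_abs = abs(t)
            best_t = t
            best_subset = local
    return float(best_t), best_subset


def m_statistic(
    S: SnpSet,
    G: GenotypeMatrix,
    y: Phenotype | np.ndarray,
    method: Method = "cpca",
    config: FitConfig | None = None,
    v: int = 20,
) -> tuple[float, np.ndarray]:
    """M statistic of a SNP set: the signed t of maximal magnitude over the
    unique candidate subsets (exact ties go to the smaller subset).

    Returns (M, optimal subset as global SNP indices).
    """
    config = _pipeline_config(config)
    values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    yv = y.y if isinstance(y, Phenotype) else np.asarray(y)
    cache = _ScoreCache(values[:, S.snp_indices], method, config, config.seed)
    M, local = _m_from_cache(cache, yv, v)
    return M, S.snp_indices[local]


def permutation_null(
    S: SnpSet,
    G: GenotypeMatrix,
    prevalence: float,
    B: int,
    method: Method = "cpca",
    config: FitConfig | None = None,
    seed: int = 0,
    v: int = 20,
    m_obs: Optional[float] = None,
    early_stop_count: Optional[int] = None,
    _cache: Optional[_ScoreCache] = None,
) -> np.ndarray:
    """Null sample of M: trait labels redrawn i.i.d. Bernoulli(prevalence).

    Genotypes are untouched; each round reruns screening, subset formation
    and the M maximization.  Deterministic under ``seed``.

    When ``m_obs`` and ``early_stop_count`` are given, sampling stops as
    soon as ``early_stop_count`` null values reach |m_obs| (sequential
    Monte-Carlo testing): the returned sample may then be shorter than B.
    With the stopping count chosen so that the eventual add-one p-value
    could no longer fall below the significance level, accept/reject
    decisions are identical to the full-B run.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    config = _pipeline_config(config)
    cache = _cache or _ScoreCache(values[:, S.snp_indices], method, config, config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(S.set_id.encode())]))
    n = values.shape[0]
    out = np.empty(B)
    exceed = 0
    for b in range(B):
        M = None
        for _attempt in range(3):
            ystar = rng.binomial(1, prevalence, size=n)
            if ystar.sum() in (0, n):  # degenerate draw, redraw
                continue
            try:
                M, _ = _m_from_cache(cache, ystar.astype(float), v)
                break
            except Exception as exc:  # pragma: no cover - defensive redraw
                warnings.warn(f"permutation round failed ({exc}); redrawing")
                continue
        if M is None:
            raise RuntimeError(f"permutation round for set {S.set_id} failed 3 times")
        out[b] = M
        if m_obs is not None and early_stop_count is not None:
            if abs(M) >= abs(m_obs):
                exceed += 1
                if exceed >= early_stop_count:
                    return out[: b + 1].copy()
    return out


def empirical_pvalue(M_obs: float, null_M: np.ndarray) -> float:
    """Add-one empirical p-value: (1 + #{|M_b| >= |M_obs|}) / (B + 1)."""
    null_M = np.asarray(null_M, dtype=float)
    if null_M.size == 0:
        raise ValueError("null sample is empty")
    B = null_M.size
    return float((1 + np.sum(np.abs(null_M) >= abs(M_obs))) / (B + 1))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_snpset_analysis(
    G: GenotypeMatrix,
    y: Phenotype,
    snpsets: Sequence[SnpSet],
    method: Method = "cpca",
    B: int = 999,
    prevalence: Optional[float] = None,
    config: FitConfig | None = None,
    seed: int = 0,
    v: int = 20,
    pool_null: bool = False,
    early_stop_alpha: Optional[float] = None,
    progress: Optional[Callable[[str], None]] = None,
) -> list[AssociationResult]:
    """Full per-set analysis: observed M, permutation null, empirical and
    BH-adjusted p-values.

    ``prevalence`` defaults to the observed case fraction.  With
    ``pool_null`` the null samples of all sets are pooled before computing
    each set's empirical p-value (cross-set pooling); the default keeps a
    separate null per set.  ``early_stop_alpha`` truncates a set's
    permutations once significance at that level is excluded — decisions at
    the level are unchanged, clearly non-significant sets get approximate
    (conservative) p-values at a fraction of the cost.  Per-set failures are
    reported and skipped.
    """
    config = _pipeline_config(config)
    prev = y.case_fraction if prevalence is None else prevalence
    yv = y.y.astype(float)
    stop_count = None
    if early_stop_alpha is not None:
        if pool_null:
            raise ValueError("early stopping is incompatible with pooled nulls")
        # smallest exceedance count that pins the add-one p at or above alpha
        stop_count = int(np.ceil(early_stop_alpha * (B + 1))) - 1
        if stop_count < 1:
            stop_count = None
    results: list[AssociationResult] = []
    for S in snpsets:
        if progress:
            progress(f"set {S.set_id} ({len(S)} SNPs)")
        try:
            cache = _ScoreCache(G.values[:, S.snp_indices], method, config, config.seed)
            M, local = _m_from_cache(cache, yv, v)
            null = permutation_null(
                S, G, prev, B, method=method, config=config, seed=seed, v=v,
                m_obs=M if stop_count is not None else None,
                early_stop_count=stop_count, _cache=cache,
            )
            results.append(
                AssociationResult(
                    set_id=S.set_id,
                    n_snps=len(S),
                    M=M,
                    optimal_subset=S.snp_indices[local],
                    null_M=null,
                    p_value=np.nan,
                )
            )
        except Exception as exc:
            warnings.warn(f"SNP set {S.set_id} failed: {exc}")
    if not results:
        return results
    if pool_null:
        pooled = np.concatenate([r.null_M for r in results])
        for r in results:
            r.p_value = empirical_pvalue(r.M, pooled)
    else:
        for r in results:
            r.p_value = empirical_pvalue(r.M, r.null_M)
    adjusted = bh_adjust(np.array([r.p_value for r in results]))
    for r, pa in zip(results, adjusted):
        r.p_adjusted = float(pa)
    return results


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabular summary: set_id, n_snps, n_snps_optimal, M, p_value, p_adjusted."""
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "n_snps": [r.n_snps for r in results],
            "n_snps_optimal": [r.optimal_subset.size for r in results],
            "M": [r.M for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
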