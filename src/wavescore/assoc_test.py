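"""Windowed multilocus score test with permutation inference.

For a window of m weighted, adjusted, denoised genotype columns X (n x m,
each column centered across individuals) and a residualized trait Y, the
per-SNP scores are U(j) = sum_i X_ij Y_i with null variances
V(j) = (sum_i Y_i^2 / (n-1)) * sum_i X_ij^2, and the window statistic is
T = sum_j U(j) / V with V = sqrt(sum_j V(j)).  Empirical p-values come from
permuting the trait across individuals; family-wise corrections are either
Bonferroni on the per-window empirical p-values or comparison to the
permutation distribution of the genome-wide maximum statistic.  Because the
trait enters T only through a single inner product with the per-individual
window sums (and the trait's sum of squares is permutation-invariant),
permutation statistics for all windows reduce to one matrix product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .config import RunConfig
from .io_formats import GenotypeMatrix, PhenotypeTable
from .preprocess import (
    PCAdjustment,
    ResidualTrait,
    Window,
    compute_maf,
    fit_pca,
    make_windows,
    pc_adjust,
    residualize,
    select_num_components,
    weight_genotypes,
)
from .wavelet_denoise import WaveletConfig, denoise_matrix

logger = logging.getLogger("wavescore")

__all__ = [
    "TestConfig",
    "WindowTestResult",
    "center_window",
    "score_statistic",
    "permutation_pvalue",
    "bonferroni_correct",
    "maxstat_global_pvalue",
    "burden_baseline",
    "single_snp_scan",
    "run_pipeline",
]


@dataclass
class TestConfig:
    __test__ = False  # not a pytest collectible despite the name

    n_permutations: int = 60000
    seed: int = 0
    correction: Literal["bonferroni", "maxstat", "both"] = "bonferroni"
    link: Literal["identity", "logit"] = "identity"
    two_sided: bool = True
    add_one: bool = True  # (1+c)/(M+1) convention; False gives c/M

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class WindowTestResult:
    window: Window
    U: np.ndarray
    V_j: np.ndarray
    V: float
    T: float
    p_empirical: float
    p_bonferroni: float
    p_maxstat: float | None = None
    n_permutations: int = 0


def center_window(Xw: np.ndarray) -> np.ndarray:
    """Center each SNP column to mean zero across individuals."""
    Xw = np.asarray(Xw, dtype=float)
    if Xw.ndim == 1:
        Xw = Xw[:, None]
    if Xw.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    return Xw - Xw.mean(axis=0)


def score_statistic(
    Xw: np.ndarray, Y: ResidualTrait | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-SNP scores U(j), variances V(j), V = sqrt(sum V(j)), and T."""
    y = Y.values if isinstance(Y, ResidualTrait) else np.asarray(Y, dtype=float)
    Xw = np.asarray(Xw, dtype=float)
    if Xw.ndim == 1:
        Xw = Xw[:, None]
    n = Xw.shape[0]
    if y.shape[0] != n:
        raise ValueError(f"trait length {y.shape[0]} does not match {n} individuals")
    U = Xw.T @ y
    V_j = (y @ y / (n - 1)) * (Xw**2).sum(axis=0)
    V = float(np.sqrt(V_j.sum()))
    T = float(U.sum() / V) if V > 0 else 0.0
    return U, V_j, V, T


def bonferroni_correct(p_empirical: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_empirical * n_tests)


def _count_to_p(count: int, M: int, add_one: bool) -> float:
    return (1 + count) / (M + 1) if add_one else count / M


def _iter_perm_stats(
    S: np.ndarray, y: np.ndarray, V: np.ndarray, cfg: TestConfig, chunk: int = 1024
):
    """Yield chunks of the (M x W) matrix of permuted window statistics.

    S holds per-individual window sums (n x W); a permutation of the trait
    gives T_perm(w) = (y_perm . S[:, w]) / V(w).
    """
    rng = np.random.default_rng(cfg.seed)
    n = y.shape[0]
    safeV = np.where(V > 0, V, 1.0)
    done = 0
    while done < cfg.n_permutations:
        m = min(chunk, cfg.n_permutations - done)
        Yp = rng.permuted(np.tile(y, (m, 1)), axis=1)
        Tp = (Yp @ S) / safeV
        Tp[:, V <= 0] = 0.0
        yield np.abs(Tp) if cfg.two_sided else Tp
        done += m


def permutation_pvalue(Xw: np.ndarray, Y: ResidualTrait | np.ndarray, cfg: TestConfig) -> float:
    """Empirical p-value of one window's statistic under trait permutation."""
    Xc = center_window(Xw)
    y = Y.values if isinstance(Y, ResidualTrait) else np.asarray(Y, dtype=float)
    _, _, V, T = score_statistic(Xc, y)
    t_obs = abs(T) if cfg.two_sided else T
    S = Xc.sum(axis=1)[:, None]
    count = 0
    for Tp in _iter_perm_stats(S, y, np.array([V]), cfg):
        count += int((Tp[:, 0] >= t_obs).sum())
    return _count_to_p(count, cfg.n_permutations, cfg.add_one)


def maxstat_global_pvalue(
    T_obs: float,
    all_windows: Sequence[np.ndarray],
    Y: ResidualTrait | np.ndarray,
    cfg: TestConfig,
) -> float:
    """Global p-value of T against the permutation distribution of the
    maximum statistic over all windows (same permutations for every window)."""
    if not all_windows:
        raise ValueError("no windows")
    y = Y.values if isinstance(Y, ResidualTrait) else np.asarray(Y, dtype=float)
    Xcs = [center_window(X) for X in all_windows]
    V = np.array([score_statistic(X, y)[2] for X in Xcs])
    S = np.column_stack([X.sum(axis=1) for X in Xcs])
    t_obs = abs(T_obs) if cfg.two_sided else T_obs
    count = 0
    for Tp in _iter_perm_stats(S, y, V, cfg):
        count += int((Tp.max(axis=1) >= t_obs).sum())
    return _count_to_p(count, cfg.n_permutations, cfg.add_one)


def burden_baseline(Xw: np.ndarray, Y: ResidualTrait | np.ndarray) -> float:
    """Collapsing comparator: each individual's window is summed to a single
    weighted burden score and the one-dimensional score statistic is returned."""
    Xw = np.asarray(Xw, dtype=float)
    if Xw.ndim == 1:
        Xw = Xw[:, None]
    burden = Xw.sum(axis=1)
    _, _, _, T = score_statistic(center_window(burden), Y)
    return T


def single_snp_scan(X: np.ndarray, Y: ResidualTrait | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic per-SNP score tests: z_j = U(j)/sqrt(V(j)) and two-sided
    normal p-values.  A comparator, not part of the wavelet pipeline."""
    from scipy.stats import norm

    y = Y.values if isinstance(Y, ResidualTrait) else np.asarray(Y, dtype=float)
    Xc = center_window(X)
    U, V_j, _, _ = score_statistic(Xc, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(V_j > 0, U / np.sqrt(V_j), 0.0)
    return z, 2 * norm.sf(np.abs(z))


def _denoise_by_chromosome(values: np.ndarray, chroms: Sequence[str], wcfg: WaveletConfig) -> np.ndarray:
    out = values.copy()
    chroms = np.asarray(chroms)
    for c in dict.fromkeys(chroms.tolist()):
        cols = np.flatnonzero(chroms == c)
        if cols.size >= 2:
            out[:, cols] = denoise_matrix(values[:, cols], wcfg)
    return out


def run_pipeline(
    G: GenotypeMatrix, phenotypes: PhenotypeTable, config: RunConfig
) -> list[WindowTestResult]:
    """Full analysis: filter -> weight -> PC-adjust -> residualize ->
    denoise -> window -> permutation test -> multiple-testing correction.

    Deterministic given config.seed; genotype/phenotype individuals must
    already be aligned.
    """
    if list(G.individual_ids) != list(phenotypes.individual_ids):
        raise ValueError("genotype and phenotype individuals are not aligned")
    if config.nonsyn_only:
        keep = [j for j, s in enumerate(G.snps) if s.is_nonsynonymous]
        if not keep:
            raise ValueError("no nonsynonymous SNPs to test")
        logger.info("nonsynonymous filter: %d of %d SNPs retained", len(keep), G.n_snps)
        G = G.subset_snps(keep)
    q = compute_maf(G)
    Xw = weight_genotypes(G, q)

    adj = fit_pca(G, 0)
    k = (
        select_num_components(adj.eigenvalues[: config.pca_max_components], config.pca_ratio_threshold)
        if config.pca_k == "auto"
        else int(config.pca_k)
    )
    adj = PCAdjustment(C=adj.C, eigenvalues=adj.eigenvalues, k=k)
    logger.info("stratification adjustment with k=%d principal component(s)", k)
    Xadj = pc_adjust(Xw.values, adj)

    y_raw = pc_adjust(phenotypes.trait(config.trait), adj)
    if config.covariates:
        P = np.column_stack([pc_adjust(phenotypes.covariate(c), adj) for c in config.covariates])
    else:
        P = None
    resid = residualize(
        y_raw, P, source_trait=config.trait, model_terms=list(config.covariates),
        method=config.residual_method,
    )

    wcfg = WaveletConfig(
        family=config.wavelet_family,
        prior_scale=config.wavelet_prior_scale,
        level_dependent=config.wavelet_level_dependent,
    )
    windows = make_windows(
        G.snps, mode=config.window_mode, size=config.window_size, nonsyn_only=config.nonsyn_only
    )
    logger.info("formed %d window(s)", len(windows))
    if config.wavelet_scope == "chromosome":
        Xden = _denoise_by_chromosome(Xadj, [s.chromosome for s in G.snps], wcfg)
    else:
        Xden = Xadj.copy()
        for w in windows:
            if len(w.snp_indices) >= 2:
                Xden[:, w.snp_indices] = denoise_matrix(Xadj[:, w.snp_indices], wcfg)

    tcfg = TestConfig(
        n_permutations=config.permutations,
        seed=config.seed,
        correction=config.correction,
        two_sided=config.two_sided,
    )
    y = resid.values
    Xcs = [center_window(Xden[:, w.snp_indices]) for w in windows]
    stats = [score_statistic(X, y) for X in Xcs]
    V = np.array([s[2] for s in stats])
    T = np.array([s[3] for s in stats])
    t_obs = np.abs(T) if tcfg.two_sided else T
    S = np.column_stack([X.sum(axis=1) for X in Xcs])

    counts = np.zeros(len(windows), dtype=np.int64)
    max_counts = np.zeros(len(windows), dtype=np.int64)
    want_max = config.correction in ("maxstat", "both")
    for Tp in _iter_perm_stats(S, y, V, tcfg):
        counts += (Tp >= t_obs).sum(axis=0)
        if want_max:
            max_counts += (Tp.max(axis=1)[:, None] >= t_obs).sum(axis=0)
    logger.info("completed %d permutations for %d windows", tcfg.n_permutations, len(windows))

    results = []
    for i, w in enumerate(windows):
        p_emp = _count_to_p(int(counts[i]), tcfg.n_permutations, tcfg.add_one)
        results.append(
            WindowTestResult(
                window=w,
                U=stats[i][0],
                V_j=stats[i][1],
                V=float(V[i]),
                T=float(T[i]),
                p_empirical=p_emp,
                p_bonferroni=bonferroni_correct(p_emp, len(windows)),
                p_maxstat=_count_to_p(int(max_counts[i]), tcfg.n_permutations, tcfg.add_one)
                if want_max
                else None,
                n_permutations=tcfg.n_permutations,
            )
        )
    return results
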