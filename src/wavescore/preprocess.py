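"""MAF weighting, principal-component stratification adjustment, trait
residualization, and window construction.

The stratification correction follows the Eigenstrat convention: principal
components are computed from column-standardized dosages, and genotypes,
traits and covariates alike are replaced by their projection off the top-k
component space (M - C C'M).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io_formats import GenotypeMatrix, SnpRecord

logger = logging.getLogger("wavescore")

__all__ = [
    "PCAdjustment",
    "WeightedGenotypes",
    "ResidualTrait",
    "Window",
    "compute_maf",
    "weight_genotypes",
    "fit_pca",
    "select_num_components",
    "pc_adjust",
    "residualize",
    "make_windows",
]


@dataclass
class PCAdjustment:
    """Top-k eigenvectors of the individual covariance of standardized genotypes.

    C has orthonormal columns (n x k); eigenvalues are sorted descending and
    cover all computed components, not only the k retained ones.
    """

    C: np.ndarray
    eigenvalues: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.k < 0 or (self.C.size and self.k > self.C.shape[1]):
            raise ValueError(f"invalid component count k={self.k}")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")
        if self.k:
            gram = self.C[:, : self.k].T @ self.C[:, : self.k]
            if not np.allclose(gram, np.eye(self.k), atol=1e-8):
                raise ValueError("retained eigenvector columns are not orthonormal")

    def truncated(self) -> np.ndarray:
        return self.C[:, : self.k]


@dataclass
class WeightedGenotypes:
    """Real-valued genotype matrix after any of weighting / PC adjustment /
    wavelet denoising, with provenance flags."""

    values: np.ndarray
    weighted: bool = False
    pc_adjusted: bool = False
    denoised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("weighted genotypes must be finite")


@dataclass
class ResidualTrait:
    values: np.ndarray
    source_trait: str
    model_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("residual trait must be finite")


@dataclass
class Window:
    """An ordered group of SNP columns tested as one unit."""

    id: str
    snp_indices: list[int]
    label: str
    chromosome: str
    first_snp_id: str = ""
    last_snp_id: str = ""

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.snp_indices, self.snp_indices[1:])):
            raise ValueError(f"window {self.id}: snp indices must be strictly increasing")

    @property
    def size(self) -> int:
        return len(self.snp_indices)


def compute_maf(G: GenotypeMatrix) -> np.ndarray:
    """Estimated minor allele frequency q_j = (sum of dosages)/(2n), each in (0, 0.5]."""
    q = G.dosages.sum(axis=0) / (2.0 * G.n_individuals)
    if np.any(q <= 0) or np.any(q > 0.5):
        j = int(np.argmax((q <= 0) | (q > 0.5)))
        raise RuntimeError(
            f"SNP {G.snps[j].id}: MAF {q[j]} outside (0, 0.5] — monomorphic or "
            "unoriented columns should have been handled at read time"
        )
    return q


def weight_genotypes(G: GenotypeMatrix, q: np.ndarray) -> WeightedGenotypes:
    """Up-weight rare alleles: each dosage is divided by sqrt(n q (1-q))."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("weights undefined for q outside (0, 1)")
    n = G.n_individuals
    if n < 2:
        raise ValueError("need at least 2 individuals to weight genotypes")
    w = 1.0 / np.sqrt(n * q * (1.0 - q))
    return WeightedGenotypes(values=G.dosages * w, weighted=True)


def fit_pca(X: WeightedGenotypes | GenotypeMatrix | np.ndarray, n_components: int) -> PCAdjustment:
    """Principal components of individuals from column-standardized genotypes.

    Returns eigenvectors (columns of C) and eigenvalues of the individual x
    individual covariance M M'/p of the standardized matrix M.
    """
    if isinstance(X, GenotypeMatrix):
        M = X.dosages.astype(float)
    elif isinstance(X, WeightedGenotypes):
        M = X.values.copy()
    else:
        M = np.asarray(X, dtype=float).copy()
    n, p = M.shape
    M -= M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    nz = sd > 0
    M[:, nz] /= sd[nz]
    M[:, ~nz] = 0.0
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is {rank}")
    eigenvalues = s**2 / p
    return PCAdjustment(C=U[:, :rank], eigenvalues=eigenvalues[:rank], k=n_components)


def select_num_components(eigenvalues: Sequence[float], ratio_threshold: float = 2.0) -> int:
    """Pick k at the last big gap in the eigenvalue spectrum.

    k is the largest index j (1-based) whose eigenvalue either exceeds the
    next one by `ratio_threshold`-fold or exceeds `ratio_threshold` times the
    median of the remaining spectrum; 0 when no gap is found.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        raise ValueError("need at least two eigenvalues")
    k = 0
    for j in range(1, ev.size):
        big_ratio = ev[j] > 0 and ev[j - 1] / ev[j] >= ratio_threshold
        rest = ev[j:]
        big_vs_bulk = ev[j - 1] >= ratio_threshold * np.median(rest)
        if big_ratio or big_vs_bulk:
            k = j
    return k


def pc_adjust(M: np.ndarray, adj: PCAdjustment) -> np.ndarray:
    """Project a matrix or vector off the retained component space: M - C C'M."""
    M = np.asarray(M, dtype=float)
    if adj.k == 0:
        return M.copy()
    C = adj.truncated()
    if M.shape[0] != C.shape[0]:
        raise ValueError(f"dimension mismatch: M has {M.shape[0]} rows, C has {C.shape[0]}")
    return M - C @ (C.T @ M)


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """IRLS for logistic regression; returns fitted probabilities."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        beta_new, *_ = np.linalg.lstsq(X * w[:, None] ** 0.5, z * w**0.5, rcond=None)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return 1.0 / (1.0 + np.exp(-(X @ beta)))


def residualize(
    Y: np.ndarray,
    predictors: np.ndarray | None,
    source_trait: str = "",
    model_terms: Sequence[str] = (),
    method: Literal["ols", "logistic"] = "ols",
) -> ResidualTrait:
    """Residuals of Y regressed on predictors (with intercept).

    Default is ordinary least squares regardless of whether Y is
    quantitative or binary; `method="logistic"` subtracts fitted
    probabilities instead.  Collinear predictors are handled by the
    least-squares pseudoinverse with a logged warning.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if predictors is None or (hasattr(predictors, "size") and np.asarray(predictors).size == 0):
        P = np.empty((n, 0))
    else:
        P = np.asarray(predictors, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
    if P.shape[0] != n:
        raise ValueError("predictor rows do not match trait length")
    X = np.column_stack([np.ones(n), P])
    if P.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("collinear predictors for %s; using pseudoinverse fit", source_trait or "trait")
    if method == "logistic":
        fitted = _logistic_fit(X, Y)
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        fitted = X @ beta
    return ResidualTrait(values=Y - fitted, source_trait=source_trait, model_terms=list(model_terms))


def make_windows(
    snps: Sequence[SnpRecord],
    mode: Literal["fixed", "gene"] = "fixed",
    size: int = 8,
    nonsyn_only: bool = True,
) -> list[Window]:
    """Group SNP columns into test units.

    fixed mode: non-overlapping blocks of `size` consecutive (nonsynonymous)
    SNPs within each chromosome; a trailing partial block is kept if it has
    at least 2 SNPs.  gene mode: one window per gene holding all its
    (nonsynonymous) SNPs; genes with fewer than 2 such SNPs are skipped.
    """
    if mode == "fixed" and size < 1:
        raise ValueError("window size must be >= 1")
    eligible = [j for j, s in enumerate(snps) if s.is_nonsynonymous or not nonsyn_only]
    if not eligible:
        raise ValueError("no SNPs survive the nonsynonymous filter")
    windows: list[Window] = []
    if mode == "fixed":
        by_chrom: dict[str, list[int]] = {}
        for j in eligible:
            by_chrom.setdefault(snps[j].chromosome, []).append(j)
        for chrom, idx in by_chrom.items():
            for start in range(0, len(idx), size):
                block = idx[start : start + size]
                if len(block) < 2 and len(block) < size:
                    logger.info("dropped trailing 1-SNP window on chromosome %s", chrom)
                    continue
                first, last = snps[block[0]], snps[block[-1]]
                genes = sorted({snps[j].gene for j in block if snps[j].gene})
                windows.append(
                    Window(
                        id=f"{chrom}:{first.position}-{last.position}",
                        snp_indices=block,
                        label=",".join(genes) or f"{chrom}:{first.position}-{last.position}",
                        chromosome=chrom,
                        first_snp_id=first.id,
                        last_snp_id=last.id,
                    )
                )
    elif mode == "gene":
        by_gene: dict[str, list[int]] = {}
        for j in eligible:
            if snps[j].gene:
                by_gene.setdefault(snps[j].gene, []).append(j)
        for gene, idx in by_gene.items():
            chroms = {snps[j].chromosome for j in idx}
            if len(idx) < 2 or len(chroms) > 1:
                logger.info("skipped gene %s (%d eligible SNPs)", gene, len(idx))
                continue
            first, last = snps[idx[0]], snps[idx[-1]]
            windows.append(
                Window(
                    id=gene,
                    snp_indices=idx,
                    label=gene,
                    chromosome=first.chromosome,
                    first_snp_id=first.id,
                    last_snp_id=last.id,
                )
            )
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    if not windows:
        raise ValueError("no windows could be formed")
    windows.sort(key=lambda w: (min(w.snp_indices),))
    return windows
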