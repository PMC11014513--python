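"""PCA of standardized genotypes and local-feature diagnostics.

Genotypes are standardized by allele frequency, x_ij = (g_ij - 2 p_j) /
sqrt(2 p_j (1 - p_j)), and the top PCs are taken from the SVD X = U D V^T,
equivalently the eigendecomposition of the genetic relationship matrix
X X^T / m. PC score vectors are the unit-norm columns of U; per-variant
loadings are the columns of V (X^T u_k / d_k).

The diagnostics mirror the checks a careful GWAS analyst runs before putting
PCs in a regression model: the correlation of each PC with each variant's
dosages (peaks reveal PCs that capture a local genomic feature such as an
inversion or a region of unusual LD rather than genome-wide ancestry), the
correlation of each PC with the admixture proportion, and a simple flag that
fires when a PC is strongly correlated with some variant yet weakly
correlated with ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh, svd

__all__ = [
    "PCAResult",
    "PcDiagnostics",
    "standardize_genotypes",
    "run_pca",
    "pc_variant_correlation",
    "pc_ancestry_correlation",
    "flag_local_feature_pcs",
    "compute_diagnostics",
]


@dataclass(frozen=True)
class PCAResult:
    """Top-k PCA of a standardized genotype matrix.

    ``scores`` holds unit-norm PC score vectors u_1..u_k as columns,
    ``eigenvalues`` the eigenvalues of X X^T / m (non-increasing), and
    ``loadings`` the per-variant V columns. The sign of each PC is fixed so
    its largest-magnitude score entry is positive.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    n_variants_used: int
    regime: str = "none"

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, columns=[f"PC{i + 1}" for i in range(self.k)]
        )


@dataclass(frozen=True)
class PcDiagnostics:
    """Per-PC diagnostic summaries.

    ``pc_variant_abs_corr`` is a (k, m) array of |corr(u_k, g_j)| (NaN for
    zero-variance variants); ``pc_ancestry_corr`` the signed correlation of
    each PC with the admixture proportion; ``per_chrom_max`` the per-PC,
    per-chromosome maximum |corr|.
    """

    pc_variant_abs_corr: np.ndarray
    pc_ancestry_corr: np.ndarray
    chrom: np.ndarray
    per_chrom_max: pd.DataFrame = field(repr=False)
    local_feature_flags: np.ndarray | None = None


def standardize_genotypes(genotypes) -> np.ndarray:
    """Standardize dosages by sample allele frequency.

    x_ij = (g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)); columns have mean exactly
    zero. Monomorphic columns are an error (filter first).
    """
    g = np.asarray(genotypes, dtype=float)
    p = g.mean(axis=0) / 2.0
    bad = np.flatnonzero((p <= 0) | (p >= 1))
    if bad.size:
        raise ValueError(
            f"monomorphic variant at column {int(bad[0])}: zero variance under "
            "allele-frequency standardization"
        )
    return (g - 2 * p) / np.sqrt(2 * p * (1 - p))


def _fix_signs(scores: np.ndarray, loadings: np.ndarray):
    for k in range(scores.shape[1]):
        j = int(np.argmax(np.abs(scores[:, k])))
        if scores[j, k] < 0:
            scores[:, k] *= -1
            loadings[:, k] *= -1
    return scores, loadings


def run_pca(X, k: int = 4, regime: str = "none") -> PCAResult:
    """Top-k PCA of a standardized matrix X (n individuals x m variants).

    Uses the n x n eigendecomposition of X X^T / m when m > n (the usual
    genotype shape), otherwise a thin SVD; the two routes agree.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    if not (1 <= k <= min(n, m)):
        raise ValueError(f"k must lie in [1, min(n, m)] = [1, {min(n, m)}]")
    if m > n:
        grm = X @ X.T / m
        vals, vecs = eigh(grm, subset_by_index=(n - k, n - 1))
        order = np.argsort(vals)[::-1]
        eigenvalues = vals[order]
        scores = vecs[:, order]
        d = np.sqrt(np.maximum(eigenvalues * m, np.finfo(float).tiny))
        loadings = X.T @ scores / d
    else:
        U, s, Vt = svd(X, full_matrices=False)
        eigenvalues = (s[:k] ** 2) / m
        scores = U[:, :k]
        loadings = Vt[:k].T
    scores, loadings = _fix_signs(scores.copy(), loadings.copy())
    return PCAResult(
        scores=scores,
        eigenvalues=np.maximum(eigenvalues, 0.0),
        loadings=loadings,
        n_variants_used=m,
        regime=regime,
    )


def pc_variant_correlation(result: PCAResult, genotypes) -> np.ndarray:
    """|Pearson correlation| between each PC score vector and each dosage column.

    Zero-variance variants are reported as NaN, not zero.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] != result.scores.shape[0]:
        raise ValueError("genotypes and PC scores have different sample counts")
    gc = g - g.mean(axis=0)
    gn = np.sqrt((gc**2).sum(axis=0))
    uc = result.scores - result.scores.mean(axis=0)
    un = np.sqrt((uc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (uc.T @ gc) / np.outer(un, gn)
    corr[:, gn == 0] = np.nan
    return np.abs(corr)


def pc_ancestry_correlation(result: PCAResult, pi) -> np.ndarray:
    """Signed Pearson correlation of each PC score vector with pi."""
    pi = np.asarray(pi, dtype=float)
    if len(pi) != result.scores.shape[0]:
        raise ValueError("pi and PC scores have different lengths")
    if np.std(pi) == 0:
        raise ValueError("pi is constant; correlation with PCs is undefined")
    pc = pi - pi.mean()
    uc = result.scores - result.scores.mean(axis=0)
    return (uc.T @ pc) / (
        np.sqrt((uc**2).sum(axis=0)) * np.sqrt((pc**2).sum())
    )


def flag_local_feature_pcs(
    diag: PcDiagnostics,
    corr_peak_threshold: float = 0.3,
    ancestry_corr_floor: float = 0.5,
) -> np.ndarray:
    """Flag PCs that look like local-feature PCs.

    A PC is flagged iff its maximum |corr| with any single variant reaches
    ``corr_peak_threshold`` while its |corr| with the admixture proportion
    stays below ``ancestry_corr_floor`` — a peaked loading profile without a
    genome-wide ancestry signal.
    """
    peak = np.nanmax(diag.pc_variant_abs_corr, axis=1)
    return (peak >= corr_peak_threshold) & (
        np.abs(diag.pc_ancestry_corr) < ancestry_corr_floor
    )


def compute_diagnostics(
    result: PCAResult,
    genotypes,
    pi,
    chrom,
    corr_peak_threshold: float = 0.3,
    ancestry_corr_floor: float = 0.5,
) -> PcDiagnostics:
    """PC-variant and PC-ancestry correlations plus local-feature flags."""
    abs_corr = pc_variant_correlation(result, genotypes)
    anc = pc_ancestry_correlation(result, pi)
    chrom = np.asarray(chrom, dtype=str)
    rows = []
    for c in pd.unique(chrom):
        sub = abs_corr[:, chrom == c]
        rows.append([c] + list(np.nanmax(sub, axis=1)))
    per_chrom = pd.DataFrame(
        rows, columns=["chrom"] + [f"PC{i + 1}" for i in range(result.k)]
    )
    diag = PcDiagnostics(
        pc_variant_abs_corr=abs_corr,
        pc_ancestry_corr=anc,
        chrom=chrom,
        per_chrom_max=per_chrom,
    )
    flags = flag_local_feature_pcs(diag, corr_peak_threshold, ancestry_corr_floor)
    return PcDiagnostics(
        pc_variant_abs_corr=abs_corr,
        pc_ancestry_corr=anc,
        chrom=chrom,
        per_chrom_max=per_chrom,
        local_feature_flags=flags,
    )
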