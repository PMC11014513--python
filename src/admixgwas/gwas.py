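"""Trait simulation and marginal-regression genome scans.

The trait model is y_i = beta1 * g_i1 + beta_pi * pi_i + e_i with standard
normal noise: a single causal variant plus an optional direct effect of
global ancestry. Association testing fits, at every variant j, the marginal
linear model E[y | g_j, w] = alpha + beta_j g_j + gamma' w for a chosen
covariate vector w (nothing, the admixture proportion, PC scores, or an
"artificial PC" built from two named variants), and refers the Wald
statistic beta_hat / se to the standard normal.

The genome scan uses the Frisch-Waugh-Lovell decomposition: y and every
genotype column are residualized on [1, w] once, after which each per-variant
fit is a simple regression. This is algebraically identical to per-variant
OLS with homoskedastic standard errors and fast enough for replicated
simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .pca import PCAResult

__all__ = [
    "TraitParams",
    "CovariateSpec",
    "ArtificialPcSpec",
    "CollinearityError",
    "simulate_trait",
    "build_covariates",
    "fit_marginal",
    "run_gwas",
    "scan",
    "count_spurious",
    "genomic_control_lambda",
    "CHI2_1_MEDIAN",
    "GENOME_WIDE_ARRAY",
    "GENOME_WIDE_SEQUENCE",
]

GENOME_WIDE_ARRAY = 5e-8
GENOME_WIDE_SEQUENCE = 5e-9
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


class CollinearityError(ValueError):
    """Raised when a tested variant is collinear with the covariates."""


@dataclass(frozen=True)
class TraitParams:
    """Trait-model coefficients; the residual standard deviation is fixed at 1."""

    causal_index: int
    beta1: float
    beta_pi: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self):
        if self.residual_sd != 1.0:
            raise ValueError("residual_sd is fixed at 1 in the trait model")


@dataclass(frozen=True)
class ArtificialPcSpec:
    """An artificial PC loading on two variants on distinct chromosomes.

    z = weight_a * std(g_a) + weight_b * std(g_b) + Normal(0, noise_sd^2),
    where std() standardizes to zero mean and unit variance in sample.
    """

    variant_a: int
    variant_b: int
    weight_a: float = 1.0
    weight_b: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CovariateSpec:
    """Which covariates to place in the marginal model.

    kind: 'none', 'ancestry' (admixture proportion), 'pcs' (first k PC
    scores), or 'artificial' ([pi, z] with z from ``artificial``).
    """

    kind: str = "none"
    k: int = 1
    regime: str = "none"
    artificial: ArtificialPcSpec | None = None

    def __post_init__(self):
        if self.kind not in ("none", "ancestry", "pcs", "artificial"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "pcs" and self.k < 1:
            raise ValueError("k must be >= 1 for kind='pcs'")
        if self.kind == "artificial" and self.artificial is None:
            raise ValueError("kind='artificial' requires an ArtificialPcSpec")


def simulate_trait(genotypes, pi, params: TraitParams, seed: int = 0) -> np.ndarray:
    """Draw a trait vector from the single-causal-variant model."""
    g = np.asarray(genotypes)
    pi = np.asarray(pi, dtype=float)
    if not (0 <= params.causal_index < g.shape[1]):
        raise ValueError(
            f"causal_index {params.causal_index} out of range for m={g.shape[1]}"
        )
    rng = substream(seed, "trait")
    eps = rng.standard_normal(g.shape[0])
    return params.beta1 * g[:, params.causal_index] + params.beta_pi * pi + eps


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("cannot standardize a constant variant")
    return (v - v.mean()) / s


def build_covariates(
    spec: CovariateSpec,
    pca: PCAResult | None = None,
    pi=None,
    genotypes=None,
    chrom=None,
    seed: int = 0,
) -> np.ndarray:
    """Assemble the covariate matrix w (n x q; q may be 0)."""
    if spec.kind == "none":
        n = None
        for src in (pi, genotypes, pca.scores if pca is not None else None):
            if src is not None:
                n = np.asarray(src).shape[0]
                break
        if n is None:
            raise ValueError("cannot infer sample count for empty covariates")
        return np.empty((n, 0))
    if spec.kind == "ancestry":
        if pi is None:
            raise ValueError("kind='ancestry' requires pi")
        return np.asarray(pi, dtype=float).reshape(-1, 1)
    if spec.kind == "pcs":
        if pca is None:
            raise ValueError("kind='pcs' requires a PCAResult")
        if spec.k > pca.k:
            raise ValueError(f"requested {spec.k} PCs but PCA holds {pca.k}")
        return pca.scores[:, : spec.k].copy()
    # artificial
    art = spec.artificial
    if genotypes is None or pi is None:
        raise ValueError("kind='artificial' requires genotypes and pi")
    g = np.asarray(genotypes, dtype=float)
    if chrom is not None:
        chrom = np.asarray(chrom, dtype=str)
        if chrom[art.variant_a] == chrom[art.variant_b]:
            raise ValueError(
                "artificial PC variants must sit on distinct chromosomes"
            )
    rng = substream(seed, "artificial_pc")
    z = art.weight_a * _standardize(g[:, art.variant_a]) + art.weight_b * _standardize(
        g[:, art.variant_b]
    )
    if art.noise_sd > 0:
        z = z + rng.normal(0.0, art.noise_sd, size=len(z))
    return np.column_stack([np.asarray(pi, dtype=float), z])


class MarginalFit(NamedTuple):
    beta_hat: float
    se: float
    wald: float
    pvalue: float


def fit_marginal(y, g_j, w=None) -> MarginalFit:
    """OLS fit of y on [1, g_j, w] with homoskedastic standard errors.

    The Wald statistic beta_hat/se is referred to the standard normal
    (two-sided). Raises :class:`CollinearityError` when g_j lies in the span
    of [1, w].
    """
    y = np.asarray(y, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    w = np.empty((len(y), 0)) if w is None else np.asarray(w, dtype=float)
    X = np.column_stack([np.ones(len(y)), g_j, w])
    n, p = X.shape
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if np.any(diag < max(n, p) * np.finfo(float).eps * diag.max()):
        raise CollinearityError(
            "tested variant is collinear with the covariates (rank-deficient design)"
        )
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    dof = n - p
    sigma2 = resid @ resid / dof if dof > 0 else 0.0
    rinv = np.linalg.inv(r)
    var_beta = sigma2 * (rinv @ rinv.T)[1, 1]
    se = float(np.sqrt(var_beta))
    beta = float(coef[1])
    wald = beta / se if se > 0 else np.sign(beta) * np.inf
    pvalue = float(2 * stats.norm.sf(abs(wald)))
    return MarginalFit(beta, se, wald, pvalue)


def _residualize(w: np.ndarray, *mats):
    """Residualize each matrix on [1, w] via an orthonormal basis."""
    n = mats[0].shape[0]
    design = np.column_stack([np.ones(n), w])
    q, _ = np.linalg.qr(design)
    return [m - q @ (q.T @ m) for m in mats], design.shape[1]


def scan(Y, genotypes, w=None):
    """Vectorized marginal scan for one or more traits.

    Parameters: Y (n,) or (n, r) traits, genotypes (n, m), w (n, q) or None.
    Returns dict of (m, r) arrays beta/se/wald/pvalue (collinear variants are
    NaN). Identical to per-variant :func:`fit_marginal` by the FWL theorem.
    """
    G = np.asarray(genotypes, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, m = G.shape
    w = np.empty((n, 0)) if w is None else np.asarray(w, dtype=float)
    (G_r, Y_r), p_cov = _residualize(w, G, Y)
    gss = (G_r**2).sum(axis=0)
    scale = (G**2).sum(axis=0).max()
    ok = gss > scale * np.finfo(float).eps * n
    yss = (Y_r**2).sum(axis=0)
    dof = n - (p_cov + 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G_r.T @ Y_r) / gss[:, None]
        rss = yss[None, :] - beta**2 * gss[:, None]
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / dof / gss[:, None])
        wald = beta / se
    beta[~ok] = np.nan
    se[~ok] = np.nan
    wald[~ok] = np.nan
    pvalue = 2 * stats.norm.sf(np.abs(wald))
    out = {"beta": beta, "se": se, "wald": wald, "pvalue": pvalue}
    if squeeze:
        out = {k: v[:, 0] for k, v in out.items()}
    return out


def run_gwas(y, genotypes, w=None, chrom=None, pos_bp=None) -> pd.DataFrame:
    """Per-variant marginal association scan; returns a tidy result table.

    Columns: chrom, pos_bp, beta, se, wald, pvalue. Variants collinear with
    the covariates are reported with missing statistics rather than dropped.
    """
    G = np.asarray(genotypes, dtype=float)
    m = G.shape[1]
    res = scan(y, G, w)
    chrom = np.asarray(chrom, dtype=str) if chrom is not None else np.full(m, "0")
    pos = (
        np.asarray(pos_bp, dtype=np.int64)
        if pos_bp is not None
        else np.arange(1, m + 1)
    )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": pos,
            "beta": res["beta"],
            "se": res["se"],
            "wald": res["wald"],
            "pvalue": res["pvalue"],
        }
    )


def count_spurious(
    results: pd.DataFrame, causal_chrom, threshold: float = GENOME_WIDE_ARRAY
) -> int:
    """Chromosomes (excluding the causal one) with >= 1 variant at p < threshold.

    Spurious associations are counted at the chromosome level because nearby
    variants in LD show near-identical association signals; the comparison is
    strict (p exactly at the threshold does not count).
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    sig = results[results["pvalue"] < threshold]
    return int(sig.loc[sig["chrom"] != str(causal_chrom), "chrom"].nunique())


def genomic_control_lambda(results) -> float:
    """Genomic-control inflation factor: median(wald^2) / median(chi^2_1)."""
    if isinstance(results, pd.DataFrame):
        wald = results["wald"].to_numpy()
    else:
        wald = np.asarray(results, dtype=float)
    wald = wald[np.isfinite(wald)]
    if wald.size == 0:
        raise ValueError("no valid Wald statistics")
    return float(np.median(wald**2) / CHI2_1_MEDIAN)
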