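"""Analytic expected effect sizes under each ancestry-adjustment strategy.

Works at the level of population moments. Under the generating model
(two ancestral populations; each allele copy from population 1 with
probability pi; trait y = beta1 g1 + beta_pi pi + e), the first and second
moments of (g1, g2, pi, z) have closed forms:

    E[g_k]        = 2 (p_k0 + d_k mu),            d_k = p_k1 - p_k0
    Var(g_k)      = 2 q_k (1 - q_k) + 2 d_k^2 V,  q_k = p_k0 + d_k mu
    Cov(g_k, pi)  = 2 d_k V
    Cov(g_1, g_2) = 4 d_1 d_2 V      (variants independent given pi)

with mu = E[pi] and V = Var(pi); only the first two moments of pi enter. The
extraneous covariate z (the "artificial PC") is linear in the standardized
genotypes plus independent noise, so its moments propagate linearly.

The large-sample expectation of the per-variant OLS estimate is the
coefficient of the tested variant in the population least-squares projection
of y on [1, g_test, w]; it is obtained by solving the moment-based normal
equations. This is exact under the stated model and serves as the reference
for the simulation modules. Closed forms for the simple unadjusted cases are
kept as cross-checks in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "ExtraneousCovariateSpec",
    "TheoryModel",
    "Moments",
    "ExpectedEstimate",
    "SingularModelError",
    "genotype_moments",
    "expected_coefficients",
    "bias_conditions",
    "bias_magnitude_surface",
    "ADJUSTMENTS",
]

ADJUSTMENTS = ("none", "ancestry", "pcs", "artificial")


class SingularModelError(ValueError):
    """Raised when the covariate moment matrix is singular."""


@dataclass(frozen=True)
class ExtraneousCovariateSpec:
    """Construction of the extraneous covariate z.

    z = weight_causal * std(g1) + weight_neutral * std(g2) + Normal(0,
    noise_sd^2). Setting a weight to zero severs the corresponding arrow in
    the collider diagram.
    """

    weight_causal: float = 1.0
    weight_neutral: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TheoryModel:
    """Model parameters from which expected estimates are computed.

    p10/p11: causal-variant (Variant 1) frequencies in populations 0/1;
    p20/p21: the unlinked neutral variant (Variant 2); pi_mean/pi_var: the
    admixture-proportion moments; beta1/beta_pi: trait-model effects;
    z_spec: optional extraneous-covariate construction.
    """

    p10: float
    p11: float
    p20: float
    p21: float
    pi_mean: float = 0.8
    pi_var: float = 0.01
    beta1: float = 1.0
    beta_pi: float = 0.0
    z_spec: ExtraneousCovariateSpec | None = None

    def __post_init__(self):
        for name in ("p10", "p11", "p20", "p21"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.pi_mean < 1.0):
            raise ValueError("pi_mean must lie in (0, 1)")
        cap = self.pi_mean * (1 - self.pi_mean)
        if not (0.0 <= self.pi_var <= cap):
            raise ValueError(f"pi_var must lie in [0, {cap:.4g}]")

    @property
    def d1(self) -> float:
        return self.p11 - self.p10

    @property
    def d2(self) -> float:
        return self.p21 - self.p20


@dataclass(frozen=True)
class Moments:
    """First and second moments of (g1, g2, pi, z).

    ``mean`` is indexed by variable name; ``cov`` is the 4x4 (or 3x3 when no
    z) covariance matrix over ``names``. ``cond_cov_g1_z``/``cond_cov_g2_z``
    are the pi-conditional covariances E[Cov(g_k, z | pi)] that govern the
    collider pathway.
    """

    names: tuple
    mean: dict
    cov: pd.DataFrame
    cond_cov_g1_z: float | None = None
    cond_cov_g2_z: float | None = None


def genotype_moments(model: TheoryModel) -> Moments:
    """Exact moments of (g1, g2, pi[, z]) under the generating model."""
    mu, V = model.pi_mean, model.pi_var
    d1, d2 = model.d1, model.d2
    q1 = model.p10 + d1 * mu
    q2 = model.p20 + d2 * mu
    mean = {"g1": 2 * q1, "g2": 2 * q2, "pi": mu}
    var_g1 = 2 * q1 * (1 - q1) + 2 * d1**2 * V
    var_g2 = 2 * q2 * (1 - q2) + 2 * d2**2 * V
    cov12 = 4 * d1 * d2 * V
    cov1pi = 2 * d1 * V
    cov2pi = 2 * d2 * V
    names = ["g1", "g2", "pi"]
    cov = np.array(
        [
            [var_g1, cov12, cov1pi],
            [cov12, var_g2, cov2pi],
            [cov1pi, cov2pi, V],
        ]
    )
    cond1 = cond2 = None
    if model.z_spec is not None:
        zs = model.z_spec
        s1, s2 = np.sqrt(var_g1), np.sqrt(var_g2)
        if s1 == 0 or s2 == 0:
            raise SingularModelError("z is built on a zero-variance variant")
        wa, wb = zs.weight_causal, zs.weight_neutral
        cov_z_g1 = wa * s1 + wb * cov12 / s2
        cov_z_g2 = wa * cov12 / s1 + wb * s2
        cov_z_pi = wa * cov1pi / s1 + wb * cov2pi / s2
        var_z = (
            wa**2 + wb**2 + 2 * wa * wb * cov12 / (s1 * s2) + zs.noise_sd**2
        )
        names.append("z")
        cov = np.block(
            [
                [cov, np.array([[cov_z_g1], [cov_z_g2], [cov_z_pi]])],
                [np.array([[cov_z_g1, cov_z_g2, cov_z_pi, var_z]])],
            ]
        )
        mean["z"] = 0.0
        # E[Var(g_k | pi)] = Var(g_k) - Var(E[g_k | pi])
        evar1 = var_g1 - 4 * d1**2 * V
        evar2 = var_g2 - 4 * d2**2 * V
        cond1 = wa * evar1 / s1  # E[Cov(g1, z | pi)]; g1 _|_ g2 given pi
        cond2 = wb * evar2 / s2
    return Moments(
        names=tuple(names),
        mean=mean,
        cov=pd.DataFrame(cov, index=names, columns=names),
        cond_cov_g1_z=cond1,
        cond_cov_g2_z=cond2,
    )


@dataclass(frozen=True)
class ExpectedEstimate:
    """Large-sample expected effect estimate for one (target, adjustment) cell."""

    target: str
    adjustment: str
    expected_beta: float
    bias: float
    zero_bias_conditions: tuple


def _covariate_names(model: TheoryModel, adjustment: str) -> list:
    if adjustment == "none":
        return []
    if adjustment in ("ancestry", "pcs"):
        # The theoretical first PC is the population-limit ancestry axis, an
        # affine transform of pi; least squares is invariant to that, so the
        # two adjustments share one set of expected coefficients.
        return ["pi"]
    if adjustment == "artificial":
        if model.z_spec is None:
            raise ValueError("adjustment='artificial' requires model.z_spec")
        return ["pi", "z"]
    raise ValueError(f"unknown adjustment {adjustment!r}; expected {ADJUSTMENTS}")


def expected_coefficients(
    model: TheoryModel, adjustment: str = "none", target: str = "causal"
) -> ExpectedEstimate:
    """Expected OLS coefficient of the tested variant under an adjustment.

    Solves the population normal equations over the design [1, g_target, w],
    where Cov(y, .) follows from y = beta1 g1 + beta_pi pi + e. ``target`` is
    'causal' (Variant 1; truth beta1) or 'neutral' (Variant 2; truth 0).
    """
    if target not in ("causal", "neutral"):
        raise ValueError("target must be 'causal' or 'neutral'")
    mom = genotype_moments(model)
    g = "g1" if target == "causal" else "g2"
    names = [g] + _covariate_names(model, adjustment)
    # drop degenerate covariates (a constant is absorbed by the intercept)
    names = [names[0]] + [
        v for v in names[1:] if mom.cov.loc[v, v] > 1e-14
    ]
    sigma = mom.cov.loc[names, names].to_numpy()
    cov_y = {
        v: model.beta1 * mom.cov.loc["g1", v] + model.beta_pi * mom.cov.loc["pi", v]
        for v in names
    }
    c = np.array([cov_y[v] for v in names])
    if sigma[0, 0] <= 0:
        raise SingularModelError(f"tested variant {g} has zero variance")
    try:
        sol = np.linalg.solve(sigma, c)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError(f"singular covariate moment matrix: {exc}") from exc
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularModelError(
            "covariate moment matrix is numerically singular "
            f"(condition number {cond:.2g})"
        )
    expected = float(sol[0])
    truth = model.beta1 if target == "causal" else 0.0
    conditions = tuple(c_.description for c_ in _zero_bias_rules(adjustment, target))
    return ExpectedEstimate(
        target=target,
        adjustment=adjustment,
        expected_beta=expected,
        bias=expected - truth,
        zero_bias_conditions=conditions,
    )


# ---------------------------------------------------------------------------
# zero-bias condition catalogue


@dataclass(frozen=True)
class _Rule:
    description: str
    instantiate: callable  # TheoryModel -> TheoryModel satisfying the condition


def _set_z(model: TheoryModel, **kw) -> TheoryModel:
    if model.z_spec is None:
        raise ValueError("model has no z_spec")
    return replace(model, z_spec=replace(model.z_spec, **kw))


def _zero_bias_rules(adjustment: str, target: str) -> tuple:
    """Conditions that each individually annihilate the bias for a cell."""
    if adjustment in ("ancestry", "pcs"):
        return (
            _Rule("always (ancestry adjustment is unbiased)", lambda m: m),
        )
    if adjustment == "none" and target == "causal":
        return (
            _Rule("Var(pi) = 0 (no ancestral heterogeneity)",
                  lambda m: replace(m, pi_var=0.0)),
            _Rule("beta_pi = 0 (no direct ancestry effect)",
                  lambda m: replace(m, beta_pi=0.0)),
            _Rule("d1 = 0 (equal causal-variant ancestral frequencies)",
                  lambda m: replace(m, p11=m.p10)),
        )
    if adjustment == "none" and target == "neutral":
        return (
            _Rule("Var(pi) = 0 (no ancestral heterogeneity)",
                  lambda m: replace(m, pi_var=0.0)),
            _Rule("d2 = 0 (equal tested-variant ancestral frequencies)",
                  lambda m: replace(m, p21=m.p20)),
            _Rule("beta_pi = 0 and d1 = 0 (both ancestry-trait pathways closed)",
                  lambda m: replace(m, beta_pi=0.0, p11=m.p10)),
        )
    if adjustment == "artificial" and target == "causal":
        return (
            _Rule("always (extraneous covariate leaves the causal variant unbiased)",
                  lambda m: m),
        )
    if adjustment == "artificial" and target == "neutral":
        return (
            _Rule("Cov(g1, z | pi) = 0 (z uncorrelated with the causal variant)",
                  lambda m: _set_z(m, weight_causal=0.0)),
            _Rule("Cov(g2, z | pi) = 0 (z uncorrelated with the tested variant)",
                  lambda m: _set_z(m, weight_neutral=0.0)),
            _Rule("beta1 = 0 (no causal signal to redistribute)",
                  lambda m: replace(m, beta1=0.0)),
        )
    raise ValueError(f"no rules for ({adjustment!r}, {target!r})")


def bias_conditions(
    model: TheoryModel, adjustment: str, target: str
) -> pd.DataFrame:
    """Structured zero-bias condition report for one (adjustment, target) cell.

    Each condition is instantiated on a copy of ``model`` and verified by
    direct evaluation of :func:`expected_coefficients`; the report carries
    the residual |bias| at the instantiated point.
    """
    rows = []
    for rule in _zero_bias_rules(adjustment, target):
        modified = rule.instantiate(model)
        est = expected_coefficients(modified, adjustment, target)
        rows.append(
            {
                "adjustment": adjustment,
                "target": target,
                "condition": rule.description,
                "bias_at_condition": est.bias,
                "annihilates": abs(est.bias) < 1e-10,
            }
        )
    return pd.DataFrame(rows)


def bias_magnitude_surface(
    model: TheoryModel,
    beta1_grid=(0.0, 0.5, 1.0, 2.0, 4.0),
    weight_grid=(0.25, 0.5, 1.0, 1.5, 2.0),
    pi_var_grid=(0.0, 0.005, 0.01, 0.02, 0.04),
) -> pd.DataFrame:
    """|bias| at the neutral variant over a (beta1, z-weight, Var(pi)) grid.

    The z weights on both variants are scaled jointly by the grid value
    ("coupling strength"). The collider bias is exactly linear in the causal
    effect size and grows with the covariate-variant coupling. Ancestral
    heterogeneity drives the *confounding* pathway (the unadjusted-model
    bias is increasing in Var(pi)); under this z construction, where the
    covariate couples to the standardized genotypes directly rather than
    through ancestry, the pure collider term is insensitive to Var(pi).
    """
    if model.z_spec is None:
        raise ValueError("bias surface requires model.z_spec")
    rows = []
    for b1, wgt, pv in product(beta1_grid, weight_grid, pi_var_grid):
        m = replace(
            model,
            beta1=b1,
            pi_var=pv,
            z_spec=replace(
                model.z_spec,
                weight_causal=model.z_spec.weight_causal * wgt,
                weight_neutral=model.z_spec.weight_neutral * wgt,
            ),
        )
        est = expected_coefficients(m, "artificial", "neutral")
        rows.append(
            {"beta1": b1, "weight": wgt, "pi_var": pv, "abs_bias": abs(est.bias)}
        )
    return pd.DataFrame(rows)
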