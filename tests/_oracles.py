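"""Independent oracles used by the tests.

These implement the two-variant generating mechanism and batched OLS with
plain numpy, independently of the package's theory and gwas modules, so they
can serve as references for both.
"""

from __future__ import annotations

import numpy as np


def draw_two_variant_data(model, reps: int, n: int, rng: np.random.Generator):
    """Simulate (reps, n) draws of (g1, g2, pi, z, y) under the trait model.

    pi ~ Beta with the model's mean/variance (point mass when the variance is
    zero), each genotype Binomial(2, p_k0 + d_k pi), y = beta1 g1 +
    beta_pi pi + N(0,1), and z the weighted standardized genotypes plus
    noise when the model carries a z construction.
    """
    mu, V = model.pi_mean, model.pi_var
    if V > 0:
        nu = mu * (1 - mu) / V - 1
        pi = rng.beta(mu * nu, (1 - mu) * nu, size=(reps, n))
    else:
        pi = np.full((reps, n), mu)
    g1 = rng.binomial(2, model.p10 + model.d1 * pi).astype(float)
    g2 = rng.binomial(2, model.p20 + model.d2 * pi).astype(float)
    y = model.beta1 * g1 + model.beta_pi * pi + rng.standard_normal((reps, n))

    def std(a):
        return (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)

    cols = {"g1": g1, "g2": g2, "pi": pi, "pi_std": std(pi) if V > 0 else pi * 0}
    if model.z_spec is not None:
        zs = model.z_spec
        z = zs.weight_causal * std(g1) + zs.weight_neutral * std(g2)
        if zs.noise_sd > 0:
            z = z + zs.noise_sd * rng.standard_normal((reps, n))
        cols["z"] = z
    cols["y"] = y
    return cols


def mean_ols_beta(cols, adjustment: str, target: str):
    """Mean and MC standard error of the per-replicate OLS coefficient.

    Batched normal-equations solve of y on [1, g_target, w] for each
    replicate row.
    """
    gt = cols["g1"] if target == "causal" else cols["g2"]
    if adjustment == "none":
        w = []
    elif adjustment == "ancestry":
        w = [cols["pi"]]
    elif adjustment == "pcs":
        w = [cols["pi_std"]]
    elif adjustment == "artificial":
        w = [cols["pi"], cols["z"]]
    else:
        raise ValueError(adjustment)
    X = np.stack([np.ones_like(gt), gt] + w, axis=2)
    XtX = np.einsum("rnp,rnq->rpq", X, X)
    Xty = np.einsum("rnp,rn->rp", X, cols["y"])
    beta = np.linalg.solve(XtX, Xty[..., None])[:, 1, 0]
    return float(beta.mean()), float(beta.std(ddof=1) / np.sqrt(len(beta)))


def random_theory_model(rng: np.random.Generator, with_z: bool = True):
    """A random, well-conditioned TheoryModel draw."""
    from admixgwas.theory import ExtraneousCovariateSpec, TheoryModel

    z = None
    if with_z:
        z = ExtraneousCovariateSpec(
            weight_causal=rng.uniform(0.3, 1.2),
            weight_neutral=rng.uniform(0.3, 1.2),
            noise_sd=rng.uniform(0.0, 0.4),
        )
    return TheoryModel(
        p10=rng.uniform(0.1, 0.9),
        p11=rng.uniform(0.1, 0.9),
        p20=rng.uniform(0.1, 0.9),
        p21=rng.uniform(0.1, 0.9),
        pi_mean=rng.uniform(0.3, 0.85),
        pi_var=rng.uniform(0.002, 0.02),
        beta1=rng.uniform(0.0, 2.0),
        beta_pi=rng.uniform(-1.0, 1.0),
        z_spec=z,
    )


def brute_force_ld_prune(genotypes, chrom, pos_bp, r2_threshold, window_bp):
    """Naive reimplementation of greedy forward LD pruning (all-pairs loops)."""
    g = np.asarray(genotypes, dtype=float)
    chrom = np.asarray(chrom, dtype=str)
    pos = np.asarray(pos_bp, dtype=np.int64)
    order = np.lexsort((pos, chrom))
    kept = []
    for j in order:
        drop = False
        for k in kept:
            if chrom[k] != chrom[j] or abs(int(pos[k]) - int(pos[j])) > window_bp:
                continue
            r = np.corrcoef(g[:, k], g[:, j])[0, 1]
            if r**2 > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(int(j))
    return np.sort(np.asarray(kept, dtype=np.int64))
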