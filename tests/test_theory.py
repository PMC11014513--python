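"""Moment calculus and expected effect-size estimates under each adjustment."""

import numpy as np
import pytest

import admixgwas as ag
from admixgwas.theory import (
    ExtraneousCovariateSpec,
    SingularModelError,
    TheoryModel,
    bias_conditions,
    bias_magnitude_surface,
    expected_coefficients,
    genotype_moments,
)

from _oracles import draw_two_variant_data, mean_ols_beta, random_theory_model

GENERIC = TheoryModel(
    p10=0.1, p11=0.7, p20=0.2, p21=0.8, pi_mean=0.8, pi_var=0.01,
    beta1=2.0, beta_pi=0.5,
    z_spec=ExtraneousCovariateSpec(1.0, 1.0, 0.1),
)


class TestMoments:
    def test_no_heterogeneity_kills_ancestry_covariances(self):
        m = genotype_moments(
            TheoryModel(0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=0.0)
        )
        assert m.cov.loc["g1", "pi"] == 0.0
        assert m.cov.loc["g1", "g2"] == 0.0

    def test_equal_frequencies_kill_causal_ancestry_covariance(self):
        m = genotype_moments(
            TheoryModel(0.4, 0.4, 0.2, 0.8, pi_mean=0.8, pi_var=0.01)
        )
        assert m.cov.loc["g1", "pi"] == 0.0
        assert m.cov.loc["g2", "pi"] != 0.0

    def test_moments_match_simulation(self):
        # large-n empirical moments under the generating mechanism
        rng = np.random.default_rng(20)
        cols = draw_two_variant_data(GENERIC, reps=1, n=200_000, rng=rng)
        m = genotype_moments(GENERIC)
        g1, g2, pi, z = (cols[k][0] for k in ("g1", "g2", "pi", "z"))
        n = len(g1)
        for name, sample in (("g1", g1), ("g2", g2), ("pi", pi)):
            assert np.mean(sample) == pytest.approx(
                m.mean[name], abs=4 * np.std(sample) / np.sqrt(n)
            )
        emp = np.cov(np.vstack([g1, g2, pi, z]))
        theo = m.cov.to_numpy()
        # moment SEs ~ Var/sqrt(n); 3 MC SEs with a conservative scale
        scale = 4 * np.outer(np.sqrt(np.diag(emp)), np.sqrt(np.diag(emp)))
        np.testing.assert_allclose(emp, theo, atol=1e-8 + np.max(scale) * 3 / np.sqrt(n))

    def test_conditional_covariances_propagate_weights(self):
        m = genotype_moments(GENERIC)
        m0 = genotype_moments(
            ag.theory.TheoryModel(
                **{
                    **GENERIC.__dict__,
                    "z_spec": ExtraneousCovariateSpec(0.0, 1.0, 0.1),
                }
            )
        )
        assert m.cond_cov_g1_z > 0
        assert m0.cond_cov_g1_z == 0.0


class TestExpectedCoefficients:
    def test_ancestry_adjustment_unbiased_everywhere(self):
        for target in ("causal", "neutral"):
            est = expected_coefficients(GENERIC, "ancestry", target)
            assert est.bias == pytest.approx(0.0, abs=1e-12)

    def test_pcs_equals_ancestry(self):
        for target in ("causal", "neutral"):
            a = expected_coefficients(GENERIC, "ancestry", target)
            p = expected_coefficients(GENERIC, "pcs", target)
            assert a.expected_beta == pytest.approx(p.expected_beta, abs=1e-12)

    def test_unadjusted_neutral_closed_form(self):
        m = genotype_moments(GENERIC)
        est = expected_coefficients(GENERIC, "none", "neutral")
        closed = (
            GENERIC.beta1 * m.cov.loc["g1", "g2"]
            + GENERIC.beta_pi * m.cov.loc["pi", "g2"]
        ) / m.cov.loc["g2", "g2"]
        assert est.expected_beta == pytest.approx(closed, abs=1e-12)

    def test_unadjusted_causal_closed_form(self):
        m = genotype_moments(GENERIC)
        est = expected_coefficients(GENERIC, "none", "causal")
        closed = GENERIC.beta1 + GENERIC.beta_pi * m.cov.loc["pi", "g1"] / m.cov.loc[
            "g1", "g1"
        ]
        assert est.expected_beta == pytest.approx(closed, abs=1e-12)

    def test_no_heterogeneity_removes_confounding(self):
        m = TheoryModel(0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=0.0, beta1=2.0,
                        beta_pi=0.5)
        est = expected_coefficients(m, "none", "neutral")
        assert est.bias == pytest.approx(0.0, abs=1e-12)

    def test_extraneous_covariate_keeps_causal_unbiased(self):
        est = expected_coefficients(GENERIC, "artificial", "causal")
        assert est.bias == pytest.approx(0.0, abs=1e-10)

    def test_collider_bias_nonzero_at_neutral(self):
        est = expected_coefficients(GENERIC, "artificial", "neutral")
        assert abs(est.bias) > 0.01

    def test_noiseless_single_variant_z_is_singular(self):
        m = TheoryModel(
            0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=0.01, beta1=1.0,
            z_spec=ExtraneousCovariateSpec(1.0, 0.0, 0.0),
        )
        with pytest.raises(SingularModelError):
            expected_coefficients(m, "artificial", "causal")

    def test_matches_simulated_ols_means(self):
        # compressed version of the master oracle check (more draws in the
        # acceptance suite)
        rng = np.random.default_rng(77)
        for _ in range(3):
            model = random_theory_model(rng)
            cols = draw_two_variant_data(model, reps=1500, n=800, rng=rng)
            for adj in ("none", "ancestry", "artificial"):
                for target in ("causal", "neutral"):
                    est = expected_coefficients(model, adj, target)
                    mean, se = mean_ols_beta(cols, adj, target)
                    assert abs(mean - est.expected_beta) < 4 * se, (adj, target)


class TestBiasConditions:
    @pytest.mark.parametrize(
        "adjustment,target",
        [
            ("none", "causal"),
            ("none", "neutral"),
            ("ancestry", "causal"),
            ("ancestry", "neutral"),
            ("artificial", "causal"),
            ("artificial", "neutral"),
        ],
    )
    def test_each_condition_annihilates_bias(self, adjustment, target):
        report = bias_conditions(GENERIC, adjustment, target)
        assert len(report) >= 1
        assert report["annihilates"].all()
        assert (report["bias_at_condition"].abs() < 1e-12).all()

    def test_generic_model_is_biased_without_conditions(self):
        for adjustment, target in (("none", "causal"), ("none", "neutral"),
                                   ("artificial", "neutral")):
            est = expected_coefficients(GENERIC, adjustment, target)
            assert abs(est.bias) > 1e-6, (adjustment, target)

    def test_single_weight_severs_collider(self):
        for wa, wb in ((0.0, 1.0), (1.0, 0.0)):
            m = TheoryModel(
                0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=0.01, beta1=2.0,
                z_spec=ExtraneousCovariateSpec(wa, wb, 0.1),
            )
            est = expected_coefficients(m, "artificial", "neutral")
            assert est.bias == pytest.approx(0.0, abs=1e-12)


class TestBiasSurface:
    def test_zero_effect_size_zero_collider_bias(self):
        m = ag.theory.TheoryModel(
            0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=0.01, beta1=0.0, beta_pi=0.0,
            z_spec=ExtraneousCovariateSpec(1.0, 1.0, 0.1),
        )
        surf = bias_magnitude_surface(m, beta1_grid=(0.0,))
        assert (surf["abs_bias"] < 1e-12).all()

    def test_linearity_in_effect_size(self):
        m = ag.theory.TheoryModel(
            0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=0.01, beta1=1.0, beta_pi=0.0,
            z_spec=ExtraneousCovariateSpec(1.0, 1.0, 0.1),
        )
        b1 = expected_coefficients(m, "artificial", "neutral").bias
        m2 = ag.theory.TheoryModel(**{**m.__dict__, "beta1": 2.0})
        b2 = expected_coefficients(m2, "artificial", "neutral").bias
        assert b2 == pytest.approx(2 * b1, rel=1e-10)

    def test_monotone_in_effect_size_and_coupling(self):
        m = ag.theory.TheoryModel(
            0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=0.01, beta1=1.0, beta_pi=0.0,
            z_spec=ExtraneousCovariateSpec(1.0, 1.0, 0.3),
        )
        surf = bias_magnitude_surface(m)
        for fixed, axis in (
            (("weight", "pi_var"), "beta1"),
            (("beta1", "pi_var"), "weight"),
        ):
            for _, sub in surf.groupby(list(fixed)):
                vals = sub.sort_values(axis)["abs_bias"].to_numpy()
                assert np.all(np.diff(vals) >= -1e-12), axis

    def test_confounding_bias_increases_with_heterogeneity(self):
        # the unadjusted-model neutral bias is the pathway that scales with
        # ancestral heterogeneity
        biases = []
        for pi_var in (0.0, 0.005, 0.01, 0.02, 0.04):
            m = ag.theory.TheoryModel(
                0.1, 0.7, 0.2, 0.8, pi_mean=0.8, pi_var=pi_var, beta1=2.0,
                beta_pi=0.5,
            )
            biases.append(abs(expected_coefficients(m, "none", "neutral").bias))
        assert np.all(np.diff(biases) > 0)
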