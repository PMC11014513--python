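"""Unit and property tests for the admixed-cohort generator."""

import numpy as np
import pytest

import admixgwas as ag
from admixgwas.sim import sample_crossovers


class TestAdmixtureProportions:
    def test_zero_sd_is_point_mass(self):
        pi = ag.draw_admixture_proportions(5, mean=0.8, sd=0.0, seed=1)
        assert np.all(pi == 0.8)

    def test_large_sample_moments_match_request(self):
        pi = ag.draw_admixture_proportions(10_000, mean=0.8, sd=0.1, seed=1)
        assert abs(pi.mean() - 0.8) < 0.01
        assert abs(pi.std() - 0.1) < 0.01

    def test_seed_determinism(self):
        a = ag.draw_admixture_proportions(3, 0.8, 0.1, seed=7)
        b = ag.draw_admixture_proportions(3, 0.8, 0.1, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_moments_named_in_error(self):
        with pytest.raises(ValueError, match="sd\\^2 < mean"):
            ag.draw_admixture_proportions(10, mean=0.5, sd=0.6, seed=0)

    def test_values_in_unit_interval(self):
        pi = ag.draw_admixture_proportions(5000, 0.95, 0.02, seed=2)
        assert np.all((pi >= 0) & (pi <= 1))


class TestLocalAncestry:
    def test_pi_one_gives_all_copies(self, small_panel):
        a = ag.draw_local_ancestry(np.ones(4), small_panel, seed=0)
        assert np.all(a == 2)

    def test_independent_mode_binomial_mean(self, small_panel):
        # per-individual mean of a/2 should track pi within 3 binomial SEs
        big = ag.simulate_panel(m=2000, n_chrom=2, seed=5)
        pi = np.full(30, 0.5)
        a = ag.draw_local_ancestry(pi, big, mode="independent", seed=5)
        frac = a.mean(axis=1) / 2
        se = np.sqrt(0.5 * 0.5 / (2 * 2000))
        assert np.all(np.abs(frac - 0.5) < 3 * se + 3 * frac.std())

    def test_block_mode_crossover_rate(self):
        # Poisson oracle: 100 Mb at 1 cM/Mb = 1 Morgan; 6 generations -> mean 6
        rng = np.random.default_rng(0)
        counts = [len(sample_crossovers(rng, 0.0, 1.0, 6)) for _ in range(2000)]
        se = np.sqrt(6 / 2000)
        assert abs(np.mean(counts) - 6) < 3 * se

    def test_block_mode_marginal_mean(self, small_panel):
        pi = np.full(300, 0.7)
        a = ag.draw_local_ancestry(
            pi, small_panel, mode="block", generations=6, seed=3
        )
        # E[a_ij] = 2 pi in block mode as well
        se = np.sqrt(0.7 * 0.3 / (2 * 300 * 20))
        assert abs(a.mean() / 2 - 0.7) < 6 * se  # block correlation inflates SE

    def test_unknown_mode_rejected(self, small_panel):
        with pytest.raises(ValueError, match="mode"):
            ag.draw_local_ancestry(np.full(3, 0.5), small_panel, mode="hmm")


class TestGenotypes:
    def test_forced_allele(self, small_panel):
        panel = ag.AncestralFrequencyPanel(
            chrom=small_panel.chrom,
            pos_bp=small_panel.pos_bp,
            p0=np.ones(20),
            p1=np.ones(20),
        )
        a = ag.draw_local_ancestry(np.full(5, 0.5), panel, seed=1)
        g = ag.draw_genotypes(a, panel, seed=1)
        assert np.all(g == 2)

    def test_deterministic_given_ancestry(self, small_panel):
        panel = ag.AncestralFrequencyPanel(
            chrom=small_panel.chrom,
            pos_bp=small_panel.pos_bp,
            p0=np.zeros(20),
            p1=np.ones(20),
        )
        a = np.ones((5, 20), dtype=np.int8)
        g = ag.draw_genotypes(a, panel, seed=1)
        assert np.all(g == 1)

    def test_mixture_frequency(self):
        # E[g]/2 = pi p1 + (1 - pi) p0
        panel = ag.AncestralFrequencyPanel(
            chrom=np.array(["1"]),
            pos_bp=np.array([100]),
            p0=np.array([0.1]),
            p1=np.array([0.9]),
        )
        pi = np.full(20_000, 0.5)
        a = ag.draw_local_ancestry(pi, panel, seed=4)
        g = ag.draw_genotypes(a, panel, seed=4)
        freq = g.mean() / 2
        se = np.sqrt(0.5 * 0.5 / (2 * 20_000))
        assert abs(freq - 0.5) < 3 * se

    def test_dimension_mismatch(self, small_panel):
        with pytest.raises(ValueError, match="shape"):
            ag.draw_genotypes(np.ones((5, 3), dtype=int), small_panel)


class TestLdFeature:
    def _cohort(self, n=200, seed=2):
        panel = ag.simulate_panel(m=100, n_chrom=2, chrom_length_bp=2_000_000, seed=2)
        return panel, ag.simulate_cohort(panel, ag.SimConfig(n=n, seed=seed))

    def test_zero_coupling_is_identity(self):
        panel, cohort = self._cohort()
        spec = ag.LdFeatureSpec(
            regions=(("1", 1, 2_000_000),), coupling=0.0
        )
        out = ag.inject_ld_feature(cohort, spec, seed=3)
        np.testing.assert_array_equal(out.genotypes, cohort.genotypes)

    def test_full_coupling_copies_latent(self):
        panel, cohort = self._cohort()
        spec = ag.LdFeatureSpec(regions=(("1", 1, 2_000_000),), coupling=1.0)
        out = ag.inject_ld_feature(cohort, spec, seed=3)
        idx = np.flatnonzero(spec.variant_mask(panel))
        h = out.latent[0]
        for j in idx:
            np.testing.assert_array_equal(out.genotypes[:, j], h)
        # pairwise r^2 = 1 among replaced variants
        sub = out.genotypes[:, idx[:5]].astype(float)
        r = np.corrcoef(sub.T)
        assert np.allclose(r**2, 1.0)

    def test_partial_coupling_r2_matches_brute_force_oracle(self):
        # brute-force oracle: replicate the cell-replacement mechanism directly
        rng = np.random.default_rng(9)
        n, k, rho = 5000, 6, 0.8
        h = rng.binomial(2, 0.5, size=n)
        base = rng.binomial(2, 0.5, size=(n, k))
        mask = rng.random((n, k)) < rho
        oracle_g = np.where(mask, h[:, None], base)
        oc = np.corrcoef(oracle_g.T.astype(float))
        oracle_r2 = np.mean(oc[np.triu_indices(k, 1)] ** 2)

        panel = ag.simulate_panel(m=100, n_chrom=2, chrom_length_bp=2_000_000, seed=2)
        # a frequency-0.5, ancestry-neutral slice so the oracle matches
        panel = ag.AncestralFrequencyPanel(
            chrom=panel.chrom, pos_bp=panel.pos_bp,
            p0=np.full(100, 0.5), p1=np.full(100, 0.5),
        )
        cohort = ag.simulate_cohort(panel, ag.SimConfig(n=n, seed=4))
        spec = ag.LdFeatureSpec(regions=(("1", 1, 300_000),), coupling=rho)
        out = ag.inject_ld_feature(cohort, spec, seed=5)
        idx = np.flatnonzero(spec.variant_mask(panel))
        c = np.corrcoef(out.genotypes[:, idx].T.astype(float))
        got = np.mean(c[np.triu_indices(len(idx), 1)] ** 2)
        assert abs(got - oracle_r2) < 0.05

    def test_empty_region_warns_and_returns_unchanged(self):
        panel, cohort = self._cohort()
        spec = ag.LdFeatureSpec(regions=(("9", 1, 100),), coupling=0.5)
        with pytest.warns(UserWarning, match="no panel variants"):
            out = ag.inject_ld_feature(cohort, spec, seed=1)
        np.testing.assert_array_equal(out.genotypes, cohort.genotypes)


class TestGlobalAncestry:
    def test_boundary(self):
        assert np.all(ag.true_global_ancestry(np.full((3, 4), 2)) == 1.0)

    def test_forced_by_formula(self):
        a = np.array([[2, 1]])
        assert ag.true_global_ancestry(a)[0] == pytest.approx(0.75)

    def test_complement_identity(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=(20, 50))
        f1 = ag.true_global_ancestry(a)
        f0 = ag.true_global_ancestry(2 - a)
        np.testing.assert_allclose(f1 + f0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ag.true_global_ancestry(np.empty((3, 0)))


class TestCohortProperties:
    def test_seed_determinism_end_to_end(self, default_panel):
        c1 = ag.simulate_cohort(default_panel, ag.SimConfig(n=50, seed=123))
        c2 = ag.simulate_cohort(default_panel, ag.SimConfig(n=50, seed=123))
        np.testing.assert_array_equal(c1.genotypes, c2.genotypes)
        np.testing.assert_array_equal(c1.ancestry, c2.ancestry)
        np.testing.assert_array_equal(c1.pi, c2.pi)

    def test_sample_allele_frequency_converges_to_mixture(self, default_panel):
        cohort = ag.simulate_cohort(default_panel, ag.SimConfig(n=20_000, seed=6))
        mix = (
            cohort.pi.mean() * default_panel.p1
            + (1 - cohort.pi.mean()) * default_panel.p0
        )
        freq = cohort.allele_frequencies()
        se = np.sqrt(mix * (1 - mix) / (2 * 20_000))
        # genotype draws add ancestry variance; allow a generous multiple
        assert np.mean(np.abs(freq - mix) < 6 * se + 0.01) > 0.99

    def test_cross_chromosome_partial_correlation_vanishes(self, default_cohort):
        # conditionally on pi, variants on different chromosomes are independent
        rng = np.random.default_rng(3)
        panel = default_cohort.panel
        g = default_cohort.genotypes.astype(float)
        pi = default_cohort.pi
        design = np.column_stack([np.ones_like(pi), pi])
        q, _ = np.linalg.qr(design)
        resid = g - q @ (q.T @ g)
        vals = []
        for _ in range(100):
            j, k = rng.choice(5000, size=2, replace=False)
            if panel.chrom[j] == panel.chrom[k]:
                continue
            r = np.corrcoef(resid[:, j], resid[:, k])[0, 1]
            vals.append(r)
        # mean partial correlation ~ 0 within MC error (se ~ 1/sqrt(n)/sqrt(pairs))
        assert abs(np.mean(vals)) < 3 / np.sqrt(500 * len(vals))
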