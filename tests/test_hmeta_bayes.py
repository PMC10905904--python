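"""Hierarchical Bayesian log M-ratio: summaries, shrinkage, regression."""

import numpy as np
import pytest

import ponzometa as pm
from ponzometa.core_io import PipelineConfig
from ponzometa.hmeta_bayes import _loglik, _Data

from conftest import pooled_subject_table, simulate_flat_cohort

CFG = PipelineConfig(seed=0, chains=3, samples=1500, burn_in=500)


class TestSummarizePosterior:
    def test_degenerate_samples(self):
        s = pm.summarize_posterior(np.full(2000, 1.7))
        assert (s.map, s.hdi_low, s.hdi_high) == (1.7, 1.7, 1.7)

    def test_standard_normal_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        s = pm.summarize_posterior(x)
        # KDE mode of 1e5 draws has Monte-Carlo SD ~ 0.05; allow 2 SD
        assert s.map == pytest.approx(0.0, abs=0.1)
        assert s.hdi_low == pytest.approx(-1.96, abs=0.05)
        assert s.hdi_high == pytest.approx(1.96, abs=0.05)

    def test_hdi_width_monotone_in_mass(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, size=20_000)
        widths = []
        for mass in (0.5, 0.8, 0.9, 0.95, 0.99):
            s = pm.summarize_posterior(x, mass)
            widths.append(s.hdi_high - s.hdi_low)
        assert np.all(np.diff(widths) > 0)

    def test_hdi_shorter_than_equal_tailed_on_skewed_sample(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(size=20_000)
        s = pm.summarize_posterior(x)
        lo, hi = np.percentile(x, [2.5, 97.5])
        assert (s.hdi_high - s.hdi_low) < (hi - lo)

    @pytest.mark.parametrize("mass", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_mass_errors(self, mass):
        with pytest.raises(ValueError):
            pm.summarize_posterior(np.zeros(10), mass)


class TestHierarchicalFit:
    def test_pooled_sample_count(self):
        tabs, t1s, _ = simulate_flat_cohort(5, 5)
        post = pm.fit_hierarchical(tabs, t1s, CFG)
        assert post.mu.shape == (3, 1000)
        assert post.pooled("mu").size == 3 * (CFG.samples - CFG.burn_in)
        assert np.all(post.pooled("sigma") > 0)

    def test_shrinkage_toward_group_value(self):
        """sigma -> 0 cohort: posterior means vary less than raw MLEs."""
        rng = np.random.default_rng(8)
        tabs, t1s, mles = [], [], []
        for _ in range(15):
            tab = pooled_subject_table(rng, rng.uniform(1.0, 2.0),
                                       rng.normal(0, 0.1), -0.3)
            tabs.append(tab)
            t1s.append(pm.compute_type1(tab))
            mles.append(pm.fit_meta_d(tab, t1s[-1]).log_m_ratio)
        post = pm.fit_hierarchical(tabs, t1s, CFG)
        post_sd = post.subject_posterior_means().std()
        assert post_sd < np.nanstd(mles)

    def test_single_flat_subject_posterior_near_prior(self):
        """A single no-data subject leaves mu at its Normal(0,1) prior.

        Zero counts make the multinomial likelihood constant in the
        parameters, so the sampler must return the prior."""
        tab = pm.ConfidenceCountTable(np.zeros(8), np.zeros(8))
        t1 = pm.compute_type1(
            pm.ConfidenceCountTable([8, 0, 0, 0, 0, 0, 0, 8],
                                    [4, 0, 0, 0, 0, 0, 0, 12]))
        cfg = PipelineConfig(seed=3, chains=3, samples=3000, burn_in=1000)
        post = pm.fit_hierarchical([tab], [t1], cfg)
        mu = post.pooled("mu")
        assert abs(mu.mean()) < 0.4
        assert 0.5 < mu.std() < 1.4

    def test_grid_oracle_matches_subject_posterior_mode(self):
        """Fixed criteria, data-dominated subject: fine-grid posterior mode
        equals the MCMC subject-level mode within grid resolution."""
        crit = np.array([-1.0, -0.5, -0.2, 0.2, 0.5, 1.0])
        tab = pm.expected_count_table(1.6, 0.0, 1.2, crit[:3], crit[3:],
                                      5000, 5000)
        t1 = pm.compute_type1(tab)
        post = pm.fit_hierarchical([tab], [t1],
                                   PipelineConfig(seed=4, chains=3,
                                                  samples=3000, burn_in=1000),
                                   fix_criteria=crit[None, :])
        grid = np.arange(-1.0, 1.0, 0.01)
        ll = [
            _loglik(np.array([g]), np.zeros((1, 6)), _Data([tab], [t1]),
                    crit[None, :])[0]
            for g in grid
        ]
        grid_mode = grid[int(np.argmax(ll))]
        s = pm.summarize_posterior(post.subject_logm[:, :, 0])
        assert s.map == pytest.approx(grid_mode, abs=0.05)

    def test_convergence_flag_reports_bad_chains(self):
        tabs, t1s, _ = simulate_flat_cohort(9, 5)
        cfg = PipelineConfig(seed=0, chains=3, samples=60, burn_in=10)
        with pytest.warns(UserWarning):
            post = pm.fit_hierarchical(tabs, t1s, cfg)
        assert not post.converged


class TestRegression:
    def test_null_covariate_slope_covers_zero(self):
        tabs, t1s, _ = simulate_flat_cohort(12, 20)
        rng = np.random.default_rng(12)
        x = rng.standard_normal(20)
        post = pm.fit_hierarchical_regression(tabs, t1s, x, CFG)
        s = pm.summarize_posterior(post.pooled("beta"))
        assert s.hdi_low <= 0.0 <= s.hdi_high

    def test_slope_recovery(self):
        rng = np.random.default_rng(21)
        n = 25
        x = rng.standard_normal(n)
        xs = (x - x.mean()) / x.std()
        tabs, t1s = [], []
        for i in range(n):
            logm = -0.3 - 0.3 * xs[i] + rng.normal(0, 0.1)
            tab = pooled_subject_table(rng, rng.uniform(0.8, 2.5),
                                       rng.normal(0, 0.15), logm)
            tabs.append(tab)
            t1s.append(pm.compute_type1(tab))
        post = pm.fit_hierarchical_regression(tabs, t1s, x, CFG)
        assert post.pooled("beta").mean() == pytest.approx(-0.3, abs=0.15)

    def test_covariate_shift_invariance(self):
        tabs, t1s, _ = simulate_flat_cohort(13, 8)
        x = np.arange(8.0)
        a = pm.fit_hierarchical_regression(tabs, t1s, x, CFG, seed=99)
        b = pm.fit_hierarchical_regression(tabs, t1s, x + 100.0, CFG, seed=99)
        np.testing.assert_allclose(a.beta, b.beta)

    def test_constant_covariate_errors(self):
        tabs, t1s, _ = simulate_flat_cohort(14, 4)
        with pytest.raises(ValueError):
            pm.fit_hierarchical_regression(tabs, t1s, np.ones(4), CFG)
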