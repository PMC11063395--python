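"""Metropolis-Hastings engine, conjugate oracle, and convergence diagnostics.

The independent accuracy oracle throughout is the closed-form conjugate
posterior Beta(k+1, n-k+1), evaluated by deterministic quantile inversion;
the sampler itself never touches it.
"""

import math

import numpy as np
import pytest

from cchrbayes import (
    DegenerateChainError,
    MCMCConfig,
    beta_posterior_quantiles,
    compare_groups,
    diagnose,
    geweke_diagnostic,
    log_posterior,
    mh_sample,
    raftery_lewis,
)


class TestLogPosterior:
    def test_direct_evaluation(self):
        assert log_posterior(0.5, 1, 2) == pytest.approx(math.log(0.25))

    @pytest.mark.parametrize("p", [-0.1, 1.2])
    def test_outside_prior_support(self, p):
        assert log_posterior(p, 3, 10) == -math.inf

    def test_boundary_conventions(self):
        assert log_posterior(0.0, 0, 5) == 0.0
        assert log_posterior(1.0, 5, 5) == 0.0
        assert log_posterior(0.0, 1, 5) == -math.inf

    def test_argmax_is_mle(self):
        grid = np.linspace(1e-4, 1 - 1e-4, 20001)
        vals = [log_posterior(p, 23, 387) for p in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(23 / 387, abs=1e-3)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            log_posterior(0.5, 5, 3)
        with pytest.raises(ValueError):
            log_posterior(0.5, -1, 3)


class TestBetaQuantiles:
    def test_uniform_prior_recovery(self):
        np.testing.assert_allclose(
            beta_posterior_quantiles(0, 0, [0.025, 0.975]), [0.025, 0.975]
        )

    def test_frozen_values(self):
        np.testing.assert_allclose(
            beta_posterior_quantiles(1, 122, [0.025, 0.975]), [0.0020, 0.0445], atol=5e-4
        )
        np.testing.assert_allclose(
            beta_posterior_quantiles(23, 387, [0.5]), [0.0609], atol=5e-4
        )

    def test_invalid_probs(self):
        with pytest.raises(ValueError):
            beta_posterior_quantiles(1, 10, [0.0, 0.5])


class TestMHSample:
    def test_prior_recovery_no_data(self):
        d = mh_sample(0, 0, MCMCConfig(seed=1))
        assert abs(d.draws.mean() - 0.5) < 0.01
        assert abs(d.draws.var() - 1 / 12) < 0.01

    def test_posterior_mean_small_n(self):
        d = mh_sample(5, 10, MCMCConfig(seed=2))
        assert abs(d.draws.mean() - 0.5) < 0.02  # Beta(6,6) mean

    def test_credible_interval_matches_conjugate(self):
        d = mh_sample(23, 387, MCMCConfig(seed=3))
        lo, hi = d.credible_interval()
        exp_lo, exp_hi = beta_posterior_quantiles(23, 387, [0.025, 0.975])
        assert abs(lo - exp_lo) < 0.01
        assert abs(hi - exp_hi) < 0.01

    def test_trace_properties(self):
        cfg = MCMCConfig(iterations=2000, burn_in=500, seed=4)
        d = mh_sample(3, 50, cfg)
        assert len(d.draws) == cfg.iterations
        assert np.all((d.draws >= 0) & (d.draws <= 1))
        assert 0.0 < d.acceptance_rate < 1.0

    def test_seed_reproducibility(self):
        a = mh_sample(5, 100, MCMCConfig(seed=9))
        b = mh_sample(5, 100, MCMCConfig(seed=9))
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_acceptance_rate_in_healthy_band_for_study_strata(self):
        for k, n in [(23, 387), (1, 122), (36, 506), (9, 209)]:
            d = mh_sample(k, n, MCMCConfig(seed=11))
            assert 0.1 < d.acceptance_rate < 0.7, (k, n)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=0)
        with pytest.raises(ValueError):
            MCMCConfig(proposal_scale=-1.0)


class TestGeweke:
    def test_stationary_chain_small_z(self):
        rng = np.random.default_rng(0)
        z = geweke_diagnostic(rng.normal(0, 1, 10_000))
        assert all(abs(score) < 3 for _, score in z)

    def test_linear_drift_detected_early(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = rng.normal(0, 1, n) + np.linspace(0, 5, n)
        z = geweke_diagnostic(x)
        assert abs(z[0][1]) > 3

    def test_mean_jump_detected(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        z = geweke_diagnostic(x)
        assert max(abs(s) for _, s in z) > 3

    def test_degenerate_chain_rejected(self):
        with pytest.raises(DegenerateChainError):
            geweke_diagnostic(np.ones(5000))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(50.0))


class TestRafteryLewis:
    def test_iid_lower_bound_closed_form(self):
        rng = np.random.default_rng(3)
        *_, n_min = raftery_lewis(rng.random(5000), q=0.025, r=0.005, s=0.95)
        assert n_min == 3746

    def test_iid_lower_bound_coarse(self):
        rng = np.random.default_rng(3)
        *_, n_min = raftery_lewis(rng.random(5000), q=0.5, r=0.5, s=0.95)
        assert n_min == 4

    def test_independent_draws_near_bound(self):
        rng = np.random.default_rng(4)
        required, burn, thin, n_min = raftery_lewis(rng.random(40_000))
        assert thin == 1
        assert required < 2 * n_min

    def test_degenerate_indicator(self):
        with pytest.raises(DegenerateChainError):
            raftery_lewis(np.ones(5000))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            raftery_lewis(np.random.default_rng(0).random(5000), q=1.5)


class TestCompareGroups:
    def test_symmetry_identical_groups(self):
        r = compare_groups(5, 100, 5, 100, MCMCConfig(seed=5))
        assert abs(r.prob_a_gt_b - 0.5) < 0.02
        assert abs(r.rr_median - 1.0) < 0.1
        assert r.overlap

    def test_probability_of_difference_matches_double_integral(self):
        """P(p_a > p_b) for 23/387 vs 1/122 is ~0.992 under the exact
        product-Beta posterior (numeric double integral, frozen)."""
        r = compare_groups(23, 387, 1, 122, MCMCConfig(seed=6))
        assert r.prob_a_gt_b >= 0.98

    def test_overlapping_strata(self):
        r = compare_groups(23, 387, 36, 506, MCMCConfig(seed=7))
        assert r.overlap

    def test_direction_reversal(self):
        a = compare_groups(23, 387, 1, 122, MCMCConfig(seed=8))
        b = compare_groups(1, 122, 23, 387, MCMCConfig(seed=8))
        assert a.prob_a_gt_b + b.prob_a_gt_b == pytest.approx(1.0, abs=0.02)
        assert a.rr_median * b.rr_median == pytest.approx(1.0, rel=0.2)

    def test_prior_only_group_allowed(self):
        r = compare_groups(3, 50, 0, 0, MCMCConfig(seed=9))
        assert 0.0 < r.prob_a_gt_b < 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(-1, 10, 1, 10, MCMCConfig(seed=1))


class TestDiagnose:
    def test_convergence_gate_on_long_healthy_chain(self):
        d = mh_sample(9, 209, MCMCConfig(seed=12))
        rep = diagnose(d)
        assert rep.raftery_n_min == 3746
        assert rep.converged == (
            all(abs(z) < 2 for _, z in rep.geweke_z)
            and len(d.draws) >= rep.raftery_required_n
        )
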