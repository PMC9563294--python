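import numpy as np
import pytest

from tplnz import (AdamConfig, AdamState, TplnzSample, adam_update,
                   estimate_threshold, fit_tplnz, score_gamma, tplnz_rng,
                   TplnzParams)


def profile_loglik(gamma, pos):
    """Canonical profile log-likelihood of the positive part (test oracle)."""
    ld = np.log(pos - gamma)
    n1 = len(pos)
    s2 = ld.var()
    return -n1 / 2 * np.log(2 * np.pi * s2) - ld.sum() - n1 / 2


class TestScoreGamma:
    def test_matches_finite_difference(self, rng):
        pos = np.sort(1.0 + np.exp(rng.normal(1.0, 1.1, 50)))
        h = 1e-6 * pos[0]
        for gamma in [0.0, 0.3 * pos[0], 0.7 * pos[0]]:
            fd = (profile_loglik(gamma + h, pos)
                  - profile_loglik(gamma - h, pos)) / (2 * h) \
                if gamma > h else \
                (profile_loglik(gamma + h, pos) - profile_loglik(gamma, pos)) / h
            s = score_gamma(gamma, pos)
            assert s == pytest.approx(fd, rel=1e-4)

    def test_degenerate_equal_pair_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            score_gamma(0.0, [np.e + 1.0, np.e + 1.0])

    def test_diverges_near_smallest_observation(self, rng):
        pos = np.sort(2.0 + np.exp(rng.normal(0.5, 1.0, 30)))
        assert abs(score_gamma(pos[0] * (1 - 1e-10), pos)) > 1e6

    def test_domain_checks(self):
        pos = [1.0, 2.0, 4.0]
        with pytest.raises(ValueError):
            score_gamma(-0.1, pos)
        with pytest.raises(ValueError):
            score_gamma(1.0, pos)


class TestAdamUpdate:
    CFG = AdamConfig()

    def test_first_step_bias_correction(self):
        s1 = adam_update(AdamState(gamma=0.5), 1.0, self.CFG)
        assert s1.m == pytest.approx(0.1)
        assert s1.v == pytest.approx(0.001)
        # bias-corrected moments are (1, 1): the first step is ~ step_size
        assert 0.5 - s1.gamma == pytest.approx(
            self.CFG.step_size / (1 + self.CFG.epsilon), rel=1e-12)

    def test_zero_gradient_never_moves(self):
        state = AdamState(gamma=0.3)
        for _ in range(10):
            state = adam_update(state, 0.0, self.CFG)
        assert state.gamma == 0.3

    def test_matches_independent_reimplementation(self):
        grads = [1.0, -0.4, 0.25, 2.0, -1.5]
        cfg = self.CFG
        # straightforward re-implementation of the accumulate /
        # bias-correct / step recursion, kept separate from the package code
        m = v = 0.0
        gamma = 0.7
        states = []
        for t, g in enumerate(grads, start=1):
            m = cfg.beta1 * m + (1 - cfg.beta1) * g
            v = cfg.beta2 * v + (1 - cfg.beta2) * g * g
            gamma = gamma - cfg.step_size * (m / (1 - cfg.beta1 ** t)) / (
                np.sqrt(v / (1 - cfg.beta2 ** t)) + cfg.epsilon)
            states.append(gamma)
        state = AdamState(gamma=0.7)
        for g, want in zip(grads, states):
            state = adam_update(state, g, cfg)
            assert state.gamma == pytest.approx(want, abs=1e-12)


class TestEstimateThreshold:
    def test_profile_objective_recovers_interior_threshold(
            self, interior_sample, profile_cfg):
        gamma_hat, diag = estimate_threshold(interior_sample.positives,
                                             profile_cfg)
        assert gamma_hat == pytest.approx(3.0, abs=0.15)
        assert diag["stop_reason"] in ("grad_tol", "max_iter")

    def test_box_constraint_always_respected(self):
        for seed in range(5):
            s = tplnz_rng(TplnzParams(0.0, 2.0, 0.5, 0.9), 60, seed=seed)
            for objective in ("printed", "profile"):
                g, _ = estimate_threshold(
                    s.positives, AdamConfig(objective=objective))
                assert 0 <= g < s.x1

    def test_profile_start_point_robustness(self, interior_sample,
                                            profile_cfg):
        pos = interior_sample.positives
        g1, _ = estimate_threshold(pos, profile_cfg, gamma0=0.5 * pos[0])
        g2, _ = estimate_threshold(pos, profile_cfg, gamma0=0.9 * pos[0])
        assert abs(g1 - g2) < 10 * profile_cfg.grad_tol

    def test_printed_objective_stops_one_step_below_minimum(self, wind):
        for sample in wind.samples:
            gamma_hat, diag = estimate_threshold(sample.positives)
            assert diag["stop_reason"] == "boundary"
            assert 0 < sample.x1 - gamma_hat < 0.011 * sample.x1

    def test_profile_ascent_sanity(self, interior_sample, profile_cfg):
        pos = interior_sample.positives
        gamma_hat, _ = estimate_threshold(pos, profile_cfg)
        slack = 1e-6
        assert profile_loglik(gamma_hat, pos) >= profile_loglik(0.0, pos) - slack
        assert profile_loglik(gamma_hat, pos) >= \
            profile_loglik(0.5 * pos[0], pos) - slack


class TestFitTplnz:
    def test_zero_threshold_closed_forms(self, wind):
        sample = wind.samples[0]
        res = fit_tplnz(sample, AdamConfig(max_iter=0))
        assert res.gamma_hat == 0.0
        assert res.mu_hat == pytest.approx(np.log(sample.positives).mean())
        assert res.rho_hat == sample.n1 / sample.n

    def test_fixture_zero_percentages(self, wind):
        zp = [100 * s.zero_proportion for s in wind.samples]
        assert zp[0] == pytest.approx(13.33, abs=0.005)
        assert zp[1] == pytest.approx(8.33, abs=0.005)

    def test_profile_fit_recovers_all_parameters(self, profile_cfg):
        truth = TplnzParams(gamma=1.0, mu=1.0, sigma2=1.25, rho=0.9)
        s = tplnz_rng(truth, 5000, seed=11)
        res = fit_tplnz(s, profile_cfg)
        assert res.gamma_hat == pytest.approx(1.0, abs=0.15)
        assert abs(res.mu_hat - 1.0) < 3 * np.sqrt(1.25 / res.n1) + 0.05
        assert abs(res.sigma2_mle - 1.25) < 3 * 1.25 * np.sqrt(2 / res.n1) + 0.05
        assert abs(res.rho_hat - 0.9) < 3 * np.sqrt(0.9 * 0.1 / res.n)

    def test_order_invariance(self, rng, wind):
        sample = wind.samples[1]
        shuffled = TplnzSample.from_values(
            rng.permutation(sample.values))
        a, b = fit_tplnz(sample), fit_tplnz(shuffled)
        assert a.gamma_hat == b.gamma_hat
        assert a.mu_hat == b.mu_hat

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            fit_tplnz(TplnzSample.from_values([0.0, 0.0, 1.0, 2.0]))

    def test_sigma2_divisors(self, wind):
        res = fit_tplnz(wind.samples[0])
        assert res.sigma2_unbiased == pytest.approx(
            res.sigma2_mle * res.n1 / (res.n1 - 1), rel=1e-12)
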