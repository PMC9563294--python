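import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from tplnz import (TplnzParams, TplnzSample, median_ratio, tplnz_loglik,
                   tplnz_median, tplnz_pdf, tplnz_rng)


PARAMS = TplnzParams(gamma=2.0, mu=0.5, sigma2=1.25, rho=0.8)


class TestPdf:
    def test_atom_at_zero(self):
        p = TplnzParams(gamma=1.0, mu=0.0, sigma2=1.0, rho=0.9)
        assert tplnz_pdf(0.0, p) == pytest.approx(0.1)

    def test_zero_between_atom_and_threshold(self):
        assert tplnz_pdf(1.0, PARAMS) == 0.0
        assert tplnz_pdf(2.0, PARAMS) == 0.0

    def test_reduces_to_standard_lognormal(self):
        p = TplnzParams(gamma=0.0, mu=0.0, sigma2=1.0, rho=1 - 1e-12)
        assert tplnz_pdf(1.0, p) == pytest.approx(1 / np.sqrt(2 * np.pi),
                                                  rel=1e-9)

    def test_shifted_density_matches_lognormal(self):
        want = 0.8 * stats.lognorm.pdf(1.0, np.sqrt(1.25),
                                       scale=np.exp(0.5))
        assert tplnz_pdf(3.0, PARAMS) == pytest.approx(want, rel=1e-12)

    def test_positive_branch_integrates_to_rho(self):
        total, _ = integrate.quad(lambda x: tplnz_pdf(x, PARAMS),
                                  PARAMS.gamma, np.inf)
        assert total == pytest.approx(PARAMS.rho, abs=1e-6)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            tplnz_pdf(-0.5, PARAMS)


class TestLoglik:
    def test_equals_sum_of_log_pdf(self):
        sample = tplnz_rng(PARAMS, 60, seed=3)
        direct = sum(
            np.log(tplnz_pdf(v, PARAMS)) for v in sample.values)
        assert tplnz_loglik(PARAMS, sample) == pytest.approx(direct,
                                                             rel=1e-12)

    def test_single_observation_consistency(self):
        sample = TplnzSample.from_values([4.0])
        p = TplnzParams(gamma=0.0, mu=1.0, sigma2=1.0, rho=0.7)
        want = np.log(0.7) + stats.lognorm.logpdf(4.0, 1.0, scale=np.e)
        assert tplnz_loglik(p, sample) == pytest.approx(want, rel=1e-12)

    def test_gamma_at_or_above_minimum_rejected(self):
        sample = TplnzSample.from_values([0.0, 2.0, 3.0])
        p = TplnzParams(gamma=2.0, mu=0.0, sigma2=1.0, rho=0.5)
        with pytest.raises(ValueError):
            tplnz_loglik(p, sample)

    def test_maximized_near_truth_on_average(self):
        truth = TplnzParams(gamma=1.0, mu=1.0, sigma2=1.0, rho=0.8)
        far = TplnzParams(gamma=0.0, mu=2.5, sigma2=0.2, rho=0.3)
        wins = 0
        for seed in range(100):
            sample = tplnz_rng(truth, 20, seed=seed)
            if sample.n1 < 2:
                continue
            wins += tplnz_loglik(truth, sample) >= tplnz_loglik(far, sample)
        assert wins >= 95


class TestMedianFunctional:
    @pytest.mark.parametrize("params, want", [
        (TplnzParams(0.0, 0.0, 1.0, 1 - 1e-12), 1.0),
        (TplnzParams(1.0, 0.0, 1.0, 0.5), 1.0),
        (TplnzParams(0.399, 2.1581, 1.0, 0.8667),
         0.8667 * (0.399 + np.exp(2.1581))),
    ])
    def test_values(self, params, want):
        assert tplnz_median(params) == pytest.approx(want, rel=1e-9)

    def test_ratio_identity_and_reciprocal(self):
        p1 = TplnzParams(1.0, 1.0, 1.0, 0.9)
        p2 = TplnzParams(0.0, 1.0, 1.0, 0.9)
        assert median_ratio(p1, p1) == pytest.approx(1.0)
        assert median_ratio(p1, p2) * median_ratio(p2, p1) == \
            pytest.approx(1.0, rel=1e-12)
        assert median_ratio(p1, p2) == pytest.approx((1 + np.e) / np.e,
                                                     rel=1e-12)

    @given(st.floats(0.0, 5.0), st.floats(-1.0, 2.0),
           st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_positive_whenever_valid(self, gamma, mu, rho):
        p = TplnzParams(gamma, mu, 1.0, rho)
        assert tplnz_median(p) > 0


class TestRng:
    def test_support_above_threshold(self):
        s = tplnz_rng(TplnzParams(3.0, 1.0, 1.0, 0.8), 2000, seed=1)
        assert np.all(s.positives > 3.0)

    def test_no_zeros_in_rho_one_limit(self):
        s = tplnz_rng(TplnzParams(0.0, 0.0, 1.0, 1 - 1e-12), 10_000, seed=2)
        assert s.n0 == 0

    def test_moments_recovered(self):
        p = TplnzParams(0.0, 1.0, 1.25, 0.7)
        n = 100_000
        s = tplnz_rng(p, n, seed=7)
        se_rho = np.sqrt(0.7 * 0.3 / n)
        assert abs(s.n1 / n - 0.7) < 3 * se_rho
        logs = np.log(s.positives)
        assert abs(logs.mean() - 1.0) < 3 * np.sqrt(1.25 / s.n1)
        se_var = 1.25 * np.sqrt(2 / s.n1)
        assert abs(logs.var(ddof=1) - 1.25) < 3 * se_var

    def test_reproducible_per_seed(self):
        p = TplnzParams(1.0, 0.5, 1.0, 0.8)
        a = tplnz_rng(p, 50, seed=9)
        b = tplnz_rng(p, 50, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_sample_decomposition_invariants(self):
        s = tplnz_rng(TplnzParams(1.0, 0.5, 1.0, 0.6), 500, seed=4)
        assert s.n == s.n0 + s.n1
        assert np.all(np.diff(s.positives) >= 0)
        assert s.x1 == s.positives.min() > 0
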