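"""Bayesian credible interval for the ratio of medians.

Component posteriors, given one fitted sample:

* ``gamma`` — the conditional density proportional to
  ``exp{-sum ln(x - g) - sum (ln(x - g) - mu_hat)^2 / (2 s2_hat)}`` over
  ``[0, X_(1))`` with ``(mu_hat, s2_hat)`` plugged in; sampled by
  normalized grid inversion.
* ``rho`` — conjugate ``Beta(n1 + beta, n0 + alpha)`` under a
  ``Beta(alpha, beta)`` prior on the nonzero proportion (uniform by
  default).
* ``sigma2`` — the normal approximation centred at
  ``s2_tilde = n1 s2 / (n1 + 2)`` with variance ``2 s2_tilde^2 / (n1 + 2)``,
  truncated to positive values by resampling.
* ``mu | sigma2`` — ``Normal(mu_hat, sigma2 / n1)`` (hierarchically, using
  each sigma2 draw; a plug-in variant holds the variance at ``s2 / n1``).

``f_eta = f_rho (f_gamma + exp(f_mu))`` per group; equal-tailed empirical
percentiles of the K ratio draws give the credible interval.  sigma2 draws
enter the ratio only through the mu posterior (eta has no sigma2 term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .core import CiResult, TplnzSample
from .mle import AdamConfig, MleResult, fit_tplnz

__all__ = [
    "BayesConfig",
    "PosteriorDraws",
    "sample_gamma_posterior",
    "sample_rho_posterior",
    "sample_mu_sigma_posterior",
    "draw_posterior",
    "bayes_ci",
]


@dataclass(frozen=True)
class BayesConfig:
    """Prior and sampling settings for the Bayesian interval."""

    alpha_prior: float = 1.0
    beta_prior: float = 1.0
    k: int = 2500
    gamma_grid_points: int = 512
    mu_plugin_sigma: bool = False

    def __post_init__(self) -> None:
        if self.alpha_prior <= 0 or self.beta_prior <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.k < 1 or self.gamma_grid_points < 8:
            raise ValueError("k must be >= 1 and the grid at least 8 points")


@dataclass(frozen=True)
class PosteriorDraws:
    """K joint posterior draws for one sample."""

    f_gamma: np.ndarray
    f_rho: np.ndarray
    f_mu: np.ndarray
    f_sigma2: np.ndarray

    @property
    def f_eta(self) -> np.ndarray:
        return self.f_rho * (self.f_gamma + np.exp(self.f_mu))


def sample_gamma_posterior(positives, fit: MleResult,
                           cfg: BayesConfig | None = None,
                           seed=None) -> np.ndarray:
    """Draw K thresholds from the conditional gamma posterior."""
    cfg = cfg or BayesConfig()
    rng = np.random.default_rng(seed)
    pos = np.sort(np.asarray(positives, dtype=float))
    pos2d, n1, mask = _engine.pad_positives([pos])
    draws = _engine.gamma_posterior_draws(
        rng, pos2d, mask, n1, np.array([fit.mu_hat]),
        np.array([fit.sigma2_unbiased]), cfg.k,
        grid_points=cfg.gamma_grid_points)
    return draws[0]


def sample_rho_posterior(n0: int, n1: int, cfg: BayesConfig | None = None,
                         seed=None) -> np.ndarray:
    """Draw K nonzero proportions from Beta(n1 + beta, n0 + alpha)."""
    cfg = cfg or BayesConfig()
    rng = np.random.default_rng(seed)
    return _engine.rho_posterior_draws(rng, n0, n1, cfg.k,
                                       alpha=cfg.alpha_prior,
                                       beta=cfg.beta_prior)[0]


def sample_mu_sigma_posterior(fit: MleResult, n1: int,
                              cfg: BayesConfig | None = None,
                              seed=None):
    """Draw K (mu, sigma2) pairs from the normal-approximation posteriors.

    Returns ``(f_mu, f_sigma2)``.
    """
    cfg = cfg or BayesConfig()
    if n1 < 2:
        raise ValueError("need at least 2 positive observations")
    rng = np.random.default_rng(seed)
    f_s2, f_mu = _engine.sigma2_mu_posterior_draws(
        rng, n1, fit.mu_hat, fit.sigma2_unbiased, cfg.k,
        plugin_mu=cfg.mu_plugin_sigma)
    return f_mu[0], f_s2[0]


def draw_posterior(sample: TplnzSample, fit: MleResult,
                   cfg: BayesConfig | None = None, seed=None
                   ) -> PosteriorDraws:
    """Joint posterior draws of (gamma, rho, mu, sigma2) for one sample."""
    cfg = cfg or BayesConfig()
    rng = np.random.default_rng(seed)
    f_gamma = sample_gamma_posterior(sample.positives, fit, cfg, rng)
    f_rho = sample_rho_posterior(sample.n0, sample.n1, cfg, rng)
    f_mu, f_sigma2 = sample_mu_sigma_posterior(fit, sample.n1, cfg, rng)
    return PosteriorDraws(f_gamma=f_gamma, f_rho=f_rho, f_mu=f_mu,
                          f_sigma2=f_sigma2)


def bayes_ci(sample1: TplnzSample, sample2: TplnzSample, level: float = 0.95,
             cfg: BayesConfig | None = None,
             adam_cfg: AdamConfig | None = None, seed=None) -> CiResult:
    """Equal-tailed Bayesian credible interval for omega = eta_1 / eta_2."""
    cfg = cfg or BayesConfig()
    acfg = adam_cfg or AdamConfig()
    fit1, fit2 = fit_tplnz(sample1, acfg), fit_tplnz(sample2, acfg)
    rng = np.random.default_rng(seed)
    d1 = draw_posterior(sample1, fit1, cfg, rng)
    d2 = draw_posterior(sample2, fit2, cfg, rng)
    lo, hi = _engine.percentile_interval(d1.f_eta / d2.f_eta, level)
    return CiResult(lower=float(lo), upper=float(hi), level=level,
                    method="bayes", draws=cfg.k)
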