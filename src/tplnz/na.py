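"""Normal-approximation (NA) interval for the ratio of medians.

On the log scale ``ln eta = ln rho + ln(gamma + exp(mu))``.  The variance of
``ln eta_hat`` is estimated as

    V^MS / E^2  +  (1 - rho_hat) / (n rho_hat)

where ``V^MS`` is a distribution-free order-statistic estimate of the
variance of the sample median of the positive part, ``E = gamma_hat +
exp(mu_hat + s2 / (2 n1))`` is a plug-in expectation scale, and the second
summand is the delta-method variance of ``ln rho_hat``.  The interval is
symmetric on the log scale:

    exp[ (ln eta1_hat - ln eta2_hat) -/+ z_{1-phi/2} sqrt(V1 + V2) ].
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import _engine
from .core import CiResult, TplnzSample
from .mle import AdamConfig, MleResult, fit_tplnz

__all__ = ["median_variance_ms", "log_median_variance", "na_ci"]


def median_variance_ms(positives, *, literal_sum: bool = False):
    """Distribution-free variance of the sample median of the positives.

    ``c = floor((n1 + 1)/2 - 1.96 sqrt(n1/4))`` (clamped to >= 1) and
    ``v = ((X_(n1-c+1) - X_(c)) / (2 * 1.96))^2``.  The spread between the
    two symmetric order statistics estimates the width of a 95% interval for
    the median; ``literal_sum`` replaces the difference by a sum, matching
    the printed formula symbol-for-symbol (not location-invariant).

    Returns ``(v_ms, c)``.
    """
    pos = np.sort(np.asarray(positives, dtype=float))
    if pos.size < 5:
        raise ValueError("need at least 5 positive observations")
    if np.any(pos <= 0):
        raise ValueError("positive part contains non-positive values")
    pos2d = pos[None, :]
    mask = np.ones_like(pos2d, dtype=bool)
    v, c = _engine.ms_median_variance(pos2d, mask, np.array([pos.size]),
                                      literal_sum=literal_sum)
    return float(v[0]), int(c[0])


def log_median_variance(fit: MleResult, sample: TplnzSample,
                        *, include_rho_term: bool = True,
                        literal_sum: bool = False) -> float:
    """Estimated variance of ``ln eta_hat`` for one fitted sample.

    ``include_rho_term=False`` drops the delta-method ``ln rho_hat`` summand
    and returns ``V^MS / E^2`` alone.  A sample without zeros
    (``rho_hat = 1``) takes the zero-inflation-free limit where the
    ``ln rho_hat`` term vanishes.
    """
    if fit.rho_hat <= 0:
        raise ValueError("degenerate nonzero proportion rho_hat")
    v_ms, _ = median_variance_ms(sample.positives, literal_sum=literal_sum)
    total = _engine.na_log_eta_variance(
        fit.gamma_hat, fit.mu_hat, fit.sigma2_unbiased, fit.rho_hat,
        sample.n, sample.n1, v_ms, include_rho_term=include_rho_term)
    return float(total)


def na_ci(sample1: TplnzSample, sample2: TplnzSample, level: float = 0.95,
          adam_cfg: AdamConfig | None = None,
          *, include_rho_term: bool = True,
          literal_sum: bool = False) -> CiResult:
    """Normal-approximation interval for omega = eta_1 / eta_2.

    Deterministic given the fits (no Monte Carlo draws).
    """
    cfg = adam_cfg or AdamConfig()
    fit1, fit2 = fit_tplnz(sample1, cfg), fit_tplnz(sample2, cfg)
    v1 = log_median_variance(fit1, sample1, include_rho_term=include_rho_term,
                             literal_sum=literal_sum)
    v2 = log_median_variance(fit2, sample2, include_rho_term=include_rho_term,
                             literal_sum=literal_sum)
    d = np.log(fit1.eta_hat) - np.log(fit2.eta_hat)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    margin = z * np.sqrt(v1 + v2)
    return CiResult(lower=float(np.exp(d - margin)),
                    upper=float(np.exp(d + margin)),
                    level=level, method="na", draws=0)
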