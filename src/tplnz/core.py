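"""Zero-inflated three-parameter lognormal (TPLNZ) model.

A TPLNZ population places an atom of probability ``1 - rho`` at exactly
zero; with probability ``rho`` an observation is ``gamma + exp(Z)`` with
``Z ~ Normal(mu, sigma2)``.  The threshold ``gamma >= 0`` is the lower
bound of the positive support, so ``ln(X - gamma)`` is normal for
``X > gamma``.

The estimand throughout the package is the median functional

    eta = rho * (gamma + exp(mu)),

and, for two independent populations, the ratio ``omega = eta_1 / eta_2``.
``eta`` is the conventional summary for this model (the zero-inflation
probability times the median of the positive part); it is not the quantile
of the mixture distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


__all__ = [
    "TplnzParams",
    "TplnzSample",
    "CiResult",
    "tplnz_pdf",
    "tplnz_loglik",
    "tplnz_median",
    "median_ratio",
    "tplnz_rng",
]


@dataclass(frozen=True)
class TplnzParams:
    """Parameter vector of one TPLNZ population.

    Parameters
    ----------
    gamma : float
        Threshold (lower bound of the positive support), same units as the
        data; must be non-negative.
    mu : float
        Log-scale location of ``X - gamma``.
    sigma2 : float
        Log-scale variance; must be positive.
    rho : float
        Proportion of nonzero values, strictly inside (0, 1).
    """

    gamma: float
    mu: float
    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if not self.gamma >= 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not 0 < self.rho < 1:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")


@dataclass(frozen=True)
class TplnzSample:
    """One observed series with its zero / nonzero decomposition."""

    values: np.ndarray
    positives: np.ndarray = field(repr=False)
    n: int
    n0: int
    n1: int

    @classmethod
    def from_values(cls, values) -> "TplnzSample":
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("expected a one-dimensional series")
        if vals.size == 0:
            raise ValueError("empty sample")
        if np.any(~np.isfinite(vals)):
            raise ValueError("sample contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("sample contains negative values")
        pos = np.sort(vals[vals > 0])
        n0 = int(np.sum(vals == 0))
        return cls(values=vals, positives=pos, n=vals.size, n0=n0,
                   n1=vals.size - n0)

    @property
    def x1(self) -> float:
        """Smallest positive observation X_(1)."""
        if self.n1 == 0:
            raise ValueError("sample has no positive values")
        return float(self.positives[0])

    @property
    def zero_proportion(self) -> float:
        return self.n0 / self.n


@dataclass(frozen=True)
class CiResult:
    """A two-sided interval for the ratio of medians."""

    lower: float
    upper: float
    level: float
    method: str
    draws: int = 0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def tplnz_pdf(x, params: TplnzParams):
    """Density/mass of the TPLNZ distribution.

    Returns ``1 - rho`` at ``x == 0`` (the atom), 0 on ``0 < x <= gamma``,
    and the ``rho``-weighted lognormal density of ``x - gamma`` above the
    threshold.  Negative ``x`` raises a ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("tplnz_pdf is defined on x >= 0 only")
    out = np.zeros_like(x)
    out[x == 0] = 1.0 - params.rho
    above = x > params.gamma
    if np.any(above):
        d = x[above] - params.gamma
        z = np.log(d) - params.mu
        out[above] = (
            params.rho / (d * np.sqrt(2 * np.pi * params.sigma2))
            * np.exp(-z * z / (2 * params.sigma2))
        )
    return out if out.ndim else float(out)


def tplnz_loglik(params: TplnzParams, sample: TplnzSample) -> float:
    """Log-likelihood of a TPLNZ sample.

    Equals the sum of ``log tplnz_pdf`` over the observations: the zero
    count contributes ``n0 ln(1 - rho)``, the positive values contribute
    the lognormal log-density of ``x - gamma`` plus ``n1 ln rho``.
    Requires ``gamma < min(positives)``.
    """
    if sample.n1 > 0 and params.gamma >= sample.x1:
        raise ValueError(
            f"gamma={params.gamma} is not below the smallest positive "
            f"observation X_(1)={sample.x1}"
        )
    ll = 0.0
    if sample.n0 > 0:
        ll += sample.n0 * np.log(1.0 - params.rho)
    if sample.n1 > 0:
        d = sample.positives - params.gamma
        ld = np.log(d)
        dev = ld - params.mu
        ll += (
            sample.n1 * np.log(params.rho)
            - 0.5 * sample.n1 * np.log(2 * np.pi * params.sigma2)
            - np.sum(ld)
            - np.sum(dev * dev) / (2 * params.sigma2)
        )
    return float(ll)


def tplnz_median(params: TplnzParams) -> float:
    """Median functional ``eta = rho * (gamma + exp(mu))``."""
    return params.rho * (params.gamma + np.exp(params.mu))


def median_ratio(p1: TplnzParams, p2: TplnzParams) -> float:
    """Ratio of medians ``omega = eta_1 / eta_2``."""
    return tplnz_median(p1) / tplnz_median(p2)


def tplnz_rng(params: TplnzParams, n: int, seed=None) -> TplnzSample:
    """Draw a TPLNZ sample of size ``n``.

    Each observation is 0 with probability ``1 - rho`` and otherwise
    ``gamma + exp(Normal(mu, sigma2))``.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nonzero = rng.random(n) < params.rho
    vals = np.zeros(n)
    k = int(nonzero.sum())
    if k:
        vals[nonzero] = params.gamma + np.exp(
            rng.normal(params.mu, np.sqrt(params.sigma2), k)
        )
    return TplnzSample.from_values(vals)
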