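"""Maximum-likelihood estimation of the TPLNZ parameters.

The threshold ``gamma`` has no closed-form MLE; it is obtained by an
adaptive-moment (Adam) gradient iteration on the normalized coordinate
``u = gamma / X_(1)``.  Given ``gamma_hat``, the remaining estimates are
closed-form: ``mu_hat`` is the mean of ``ln(x - gamma_hat)`` over the
positive values, the log-scale variance is reported with both the ``n1``
(MLE) and ``n1 - 1`` (unbiased) divisors, and ``rho_hat = n1 / n``.

Two threshold objectives are available (see ``_engine`` for the full
account).  The default, ``"printed"``, reproduces the reference estimator's
behaviour: its gamma-profile increases monotonically toward the sample
minimum, so the iteration stops one Adam step below ``X_(1)``.  The
``"profile"`` objective ascends the canonical profile log-likelihood and
converges to an interior stationary point when the data exhibit one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .core import TplnzSample

__all__ = [
    "AdamConfig",
    "AdamState",
    "MleResult",
    "score_gamma",
    "adam_update",
    "estimate_threshold",
    "fit_tplnz",
]


@dataclass(frozen=True)
class AdamConfig:
    """Settings of the Adam threshold iteration.

    ``step_size`` is expressed in units of ``X_(1)`` (the iteration runs on
    ``gamma / X_(1)``), so convergence behaviour is scale-free.  ``beta1``
    and ``beta2`` are the first/second moment decay rates; ``epsilon``
    guards the denominator.  ``gamma0_fraction`` is the starting point as a
    fraction of ``X_(1)``; ``gamma_cap_fraction`` bounds the feasible box.
    """

    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    step_size: float = 0.01
    max_iter: int = 5000
    grad_tol: float = 1e-6
    gamma_cap_fraction: float = 1 - 1e-6
    gamma0_fraction: float = 0.5
    objective: str = "printed"

    def __post_init__(self) -> None:
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in [0, 1)")
        if self.step_size <= 0 or self.epsilon <= 0 or self.grad_tol <= 0:
            raise ValueError("step_size, epsilon and grad_tol must be positive")
        if not 0 < self.gamma_cap_fraction < 1:
            raise ValueError("gamma_cap_fraction must be in (0, 1)")
        if self.objective not in ("printed", "profile"):
            raise ValueError("objective must be 'printed' or 'profile'")


@dataclass(frozen=True)
class AdamState:
    """Iteration state: step count, moment accumulators, current iterate."""

    t: int = 0
    m: float = 0.0
    v: float = 0.0
    gamma: float = 0.0


@dataclass(frozen=True)
class MleResult:
    """Fitted TPLNZ parameters with optimizer diagnostics."""

    gamma_hat: float
    mu_hat: float
    sigma2_mle: float
    sigma2_unbiased: float
    rho_hat: float
    n: int
    n0: int
    n1: int
    iterations: int
    converged: bool
    stop_reason: str

    @property
    def eta_hat(self) -> float:
        """Plug-in median functional rho_hat * (gamma_hat + exp(mu_hat))."""
        return self.rho_hat * (self.gamma_hat + np.exp(self.mu_hat))

    def to_dict(self) -> dict:
        return {
            "gamma_hat": self.gamma_hat, "mu_hat": self.mu_hat,
            "sigma2_mle": self.sigma2_mle,
            "sigma2_unbiased": self.sigma2_unbiased,
            "rho_hat": self.rho_hat, "eta_hat": self.eta_hat,
            "n": self.n, "n0": self.n0, "n1": self.n1,
            "iterations": self.iterations, "converged": self.converged,
            "stop_reason": self.stop_reason,
        }


def _check_positives(positives, min_n1: int) -> np.ndarray:
    pos = np.asarray(positives, dtype=float)
    if pos.ndim != 1 or pos.size < min_n1:
        raise ValueError(f"need at least {min_n1} positive observations")
    if np.any(pos <= 0):
        raise ValueError("positive part contains non-positive values")
    return np.sort(pos)


def score_gamma(gamma: float, positives) -> float:
    """Canonical profile score for the threshold.

    The gamma-derivative of the log-likelihood with ``mu`` and ``sigma2``
    replaced by the sample moments of ``ln(x - gamma)``:

        sum 1/(x - gamma) + (n1 / S) * sum dev/(x - gamma),

    with ``dev = ln(x - gamma) - mean`` and ``S = sum dev^2``.  Requires
    ``0 <= gamma < min(positives)`` and at least two distinct positives
    (a zero within-sample log-variance makes the score undefined).
    """
    pos = _check_positives(positives, 2)
    if not 0 <= gamma < pos[0]:
        raise ValueError(
            f"gamma={gamma} outside the feasible range [0, {pos[0]})")
    ld = np.log(pos - gamma)
    dev = ld - ld.mean()
    s = np.sum(dev * dev)
    if s == 0:
        raise ValueError("degenerate data: zero within-sample log-variance")
    d = pos - gamma
    return float(np.sum(1.0 / d) + pos.size / s * np.sum(dev / d))


def adam_update(state: AdamState, grad: float, cfg: AdamConfig) -> AdamState:
    """One adaptive-moment update of the threshold iterate.

    Accumulates the decayed first and second gradient moments, applies the
    bias correction ``m / (1 - beta1^t)``, ``v / (1 - beta2^t)``, and takes
    the step ``gamma - step_size * m_hat / (sqrt(v_hat) + epsilon)``.
    """
    t = state.t + 1
    m = cfg.beta1 * state.m + (1 - cfg.beta1) * grad
    v = cfg.beta2 * state.v + (1 - cfg.beta2) * grad * grad
    m_hat = m / (1 - cfg.beta1 ** t)
    v_hat = v / (1 - cfg.beta2 ** t)
    gamma = state.gamma - cfg.step_size * m_hat / (np.sqrt(v_hat) + cfg.epsilon)
    return AdamState(t=t, m=m, v=v, gamma=float(gamma))


def estimate_threshold(positives, cfg: AdamConfig | None = None,
                       gamma0: float | None = None):
    """Estimate the threshold by the Adam iteration.

    Parameters
    ----------
    positives : array-like
        The positive observations (at least 3).
    cfg : AdamConfig
        Iteration settings; defaults reproduce the reference behaviour.
    gamma0 : float, optional
        Explicit start value (must lie in the feasible box); by default
        ``cfg.gamma0_fraction * X_(1)``.

    Returns
    -------
    (gamma_hat, diagnostics) : (float, dict)
        Diagnostics carry the iteration count, the stop reason
        (``"grad_tol" | "boundary" | "max_iter"``) and the final gradient.
    """
    cfg = cfg or AdamConfig()
    pos = _check_positives(positives, 3)
    x1 = pos[0]
    u0 = cfg.gamma0_fraction if gamma0 is None else gamma0 / x1
    if not 0 <= u0 < cfg.gamma_cap_fraction:
        raise ValueError("starting point outside the feasible box")
    pos2d, n1, mask = _engine.pad_positives([pos])
    gam, iters, stop = _engine.adam_threshold(
        pos2d, mask, n1,
        beta1=cfg.beta1, beta2=cfg.beta2, epsilon=cfg.epsilon,
        step_size=cfg.step_size, max_iter=cfg.max_iter,
        grad_tol=cfg.grad_tol, cap=cfg.gamma_cap_fraction, u0=u0,
        printed=(cfg.objective == "printed"))
    if not np.isfinite(gam[0]):
        raise RuntimeError("non-finite iterate during threshold estimation")
    gamma_hat = float(gam[0])
    if cfg.objective == "profile":
        gamma_hat = _polish_score_root(gamma_hat, pos, cfg)
        gam = np.array([gamma_hat])
    reason = {_engine.STOP_TOL: "grad_tol",
              _engine.STOP_BOUNDARY: "boundary",
              _engine.STOP_MAXIT: "max_iter"}[int(stop[0])]
    diagnostics = {
        "iterations": int(iters[0]),
        "stop_reason": reason,
        "converged": reason != "max_iter",
        "objective": cfg.objective,
        "final_gradient": float(
            _engine.batch_score(gam, pos2d, mask, n1,
                                cfg.objective == "printed")[0]),
    }
    return float(gam[0]), diagnostics


def _polish_score_root(gamma_hat: float, pos: np.ndarray,
                       cfg: AdamConfig) -> float:
    """Sharpen a profile-mode iterate to the score root it has located.

    The fixed-step Adam iteration settles within about one step of the
    stationary point; when the canonical score changes sign across a
    one-step bracket around the iterate, bisection pins the root to
    machine-level precision.  Without a sign change (threshold at a box
    boundary) the iterate is returned unchanged.
    """
    from scipy import optimize

    x1 = pos[0]
    half = cfg.step_size * x1 * 2
    lo = max(0.0, gamma_hat - half)
    hi = min(cfg.gamma_cap_fraction * x1, gamma_hat + half)
    try:
        s_lo, s_hi = score_gamma(lo, pos), score_gamma(hi, pos)
    except ValueError:
        return gamma_hat
    if s_lo * s_hi < 0:
        return float(optimize.brentq(lambda g: score_gamma(g, pos), lo, hi,
                                     xtol=1e-12 * x1))
    return gamma_hat


def fit_tplnz(sample: TplnzSample, cfg: AdamConfig | None = None) -> MleResult:
    """Fit all four TPLNZ parameters to one sample."""
    cfg = cfg or AdamConfig()
    if sample.n1 < 3:
        raise ValueError("need at least 3 positive observations to fit")
    if cfg.max_iter == 0:
        gamma_hat, diag = 0.0, {"iterations": 0, "stop_reason": "max_iter",
                                "converged": False}
    else:
        gamma_hat, diag = estimate_threshold(sample.positives, cfg)
    ld = np.log(sample.positives - gamma_hat)
    mu_hat = float(ld.mean())
    dev2 = float(np.sum((ld - mu_hat) ** 2))
    return MleResult(
        gamma_hat=gamma_hat,
        mu_hat=mu_hat,
        sigma2_mle=dev2 / sample.n1,
        sigma2_unbiased=dev2 / (sample.n1 - 1),
        rho_hat=sample.n1 / sample.n,
        n=sample.n, n0=sample.n0, n1=sample.n1,
        iterations=diag["iterations"],
        converged=diag["converged"],
        stop_reason=diag["stop_reason"],
    )
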