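"""Vectorized numerical kernels shared by the per-sample estimators and the
Monte Carlo harness.

Every kernel operates on a *batch* of samples at once: positive observations
are stored in a dense ``(B, M)`` array padded on the right, with the row
counts in ``n1``.  The per-sample public functions call these kernels with a
batch of one; the simulation harness calls them with one row per replicate,
which is what makes desk-scale coverage studies fast on a single core.

Threshold estimation
--------------------
``adam_threshold`` runs the adaptive-moment (Adam) gradient iteration on the
normalized coordinate ``u = gamma / X_(1)`` with two selectable objectives:

``printed``
    The gamma-gradient of the likelihood with a *positive* ``n1/2`` power on
    ``2*pi*sigma2`` (the form the reference estimator evidently used).  Its
    profile in gamma increases all the way to the sample minimum, so the
    iteration climbs until the next step would leave the support and returns
    the last feasible iterate — one Adam step below ``X_(1)``.  This variant
    reproduces the published wind-speed estimates and interval behaviour.

``profile``
    The canonical profile score (the derivative of the correctly signed
    log-likelihood with ``mu`` and ``sigma2`` profiled out).  This ascends to
    an interior stationary point when one exists and is the textbook local
    maximum-likelihood estimator of the threshold.

In both modes the gradient fed to the Adam update is the *negative* of the
objective's derivative (scaled by ``X_(1)``), so the subtract-the-step update
performs ascent.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# padding / moments

def pad_positives(list_of_pos) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack ragged positive-value arrays into (pos2d, n1, mask)."""
    n1 = np.array([len(p) for p in list_of_pos], dtype=np.int64)
    m = int(n1.max())
    pad = max(float(np.max([np.max(p) for p in list_of_pos])), 1.0) * 2 + 1
    pos = np.full((len(list_of_pos), m), pad)
    for i, p in enumerate(list_of_pos):
        pos[i, : n1[i]] = p
    mask = np.arange(m)[None, :] < n1[:, None]
    return pos, n1.astype(float), mask


def log_moments(pos: np.ndarray, mask: np.ndarray, n1: np.ndarray,
                gamma: np.ndarray):
    """Mean, MLE variance and unbiased variance of ln(x - gamma) per row."""
    ld = np.where(mask, np.log(np.where(mask, pos - gamma[:, None], 1.0)), 0.0)
    mu = ld.sum(1) / n1
    dev2 = np.where(mask, (ld - mu[:, None]) ** 2, 0.0).sum(1)
    return mu, dev2 / n1, dev2 / (n1 - 1)


# ---------------------------------------------------------------------------
# gamma scores

def batch_score(gamma: np.ndarray, pos: np.ndarray, mask: np.ndarray,
                n1: np.ndarray, printed: bool) -> np.ndarray:
    """Gamma-derivative of the (profiled) log-likelihood, one value per row.

    ``printed=False`` gives the canonical profile score
    ``sum 1/d + (1/s2) * sum dev/d``; ``printed=True`` flips the sign of the
    second term (positive-exponent likelihood variant).
    """
    d = np.where(mask, pos - gamma[:, None], 1.0)
    ld = np.where(mask, np.log(d), 0.0)
    mu = ld.sum(1) / n1
    dev = np.where(mask, ld - mu[:, None], 0.0)
    s2 = (dev ** 2).sum(1) / n1
    inv = np.where(mask, 1.0 / d, 0.0)
    t1 = inv.sum(1)
    t2 = (dev * inv).sum(1) / s2
    return t1 - t2 if printed else t1 + t2


def batch_profile_loglik(gamma: np.ndarray, pos: np.ndarray, mask: np.ndarray,
                         n1: np.ndarray) -> np.ndarray:
    """Canonical profile log-likelihood of the positive part at gamma."""
    d = np.where(mask, pos - gamma[:, None], 1.0)
    ld = np.where(mask, np.log(d), 0.0)
    mu = ld.sum(1) / n1
    s2 = np.where(mask, (ld - mu[:, None]) ** 2, 0.0).sum(1) / n1
    return -0.5 * n1 * np.log(2 * np.pi * s2) - ld.sum(1) - 0.5 * n1


# ---------------------------------------------------------------------------
# Adam threshold iteration

STOP_TOL = 0
STOP_BOUNDARY = 1
STOP_MAXIT = 2


def adam_threshold(pos: np.ndarray, mask: np.ndarray, n1: np.ndarray,
                   *, beta1=0.9, beta2=0.999, epsilon=1e-8, step_size=0.01,
                   max_iter=5000, grad_tol=1e-6, cap=1 - 1e-6, u0=0.5,
                   printed=True):
    """Batched Adam iteration for the threshold.

    Returns (gamma_hat, iterations, stop_code) arrays.  ``u0`` is the start
    as a fraction of X_(1); proposals below 0 are projected to 0.  Under the
    printed objective a proposal at or above ``cap`` stops that row at its
    current (feasible) iterate — the profile is monotone there, so the last
    feasible iterate is the estimate.  Under the profile objective the
    proposal is projected back to ``cap`` and iteration continues (the score
    is negative at the cap and pushes the iterate back down).
    """
    b = pos.shape[0]
    x1 = np.where(mask, pos, np.inf).min(1)
    u = np.full(b, float(u0))
    m = np.zeros(b)
    v = np.zeros(b)
    iters = np.zeros(b, dtype=np.int64)
    stop = np.full(b, STOP_MAXIT, dtype=np.int64)
    active = np.ones(b, dtype=bool)
    for t in range(1, max_iter + 1):
        score = batch_score(u * x1, pos, mask, n1, printed)
        g = -score * x1  # negative derivative: subtract-step update ascends
        hit_tol = active & (np.abs(g) < grad_tol)
        stop[hit_tol] = STOP_TOL
        iters[hit_tol] = t
        active &= ~hit_tol
        if not active.any():
            break
        m = np.where(active, beta1 * m + (1 - beta1) * g, m)
        v = np.where(active, beta2 * v + (1 - beta2) * g * g, v)
        mh = m / (1 - beta1 ** t)
        vh = v / (1 - beta2 ** t)
        prop = u - step_size * mh / (np.sqrt(vh) + epsilon)
        prop = np.maximum(prop, 0.0)
        hit_cap = active & (prop >= cap)
        if printed:
            stop[hit_cap] = STOP_BOUNDARY
            iters[hit_cap] = t
            u = np.where(active & ~hit_cap, prop, u)
            active &= ~hit_cap
            if not active.any():
                break
        else:
            u = np.where(active, np.minimum(prop, cap), u)
    iters[active] = max_iter
    return u * x1, iters, stop


# ---------------------------------------------------------------------------
# fiducial pivots

def fiducial_pivots(rng: np.random.Generator, x1, n0, n1, mu_hat, s2_unb,
                    k: int, *, literal_rho=False):
    """K fiducial pivot draws per row for (gamma, rho, mu, sigma2, eta).

    ``t_gamma ~ Uniform(0, X_(1))``; the nonzero-proportion pivot is
    ``Beta(n1 + 1, n0 + 1)`` (with ``literal_rho`` the zero-proportion pivot
    ``Beta(n0 + 1, n1 + 1)`` is used as the multiplier instead, matching the
    printed text symbol-for-symbol); ``t_sigma2 = (n1 - 1) s2_unb / V`` with
    ``V ~ chi2(n1 - 1)``; ``t_mu = mu_hat - W sqrt(t_sigma2 / n1)``.
    """
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    n0 = np.atleast_1d(np.asarray(n0, dtype=float))
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    mu_hat = np.atleast_1d(np.asarray(mu_hat, dtype=float))
    s2_unb = np.atleast_1d(np.asarray(s2_unb, dtype=float))
    b = x1.size
    shape = (b, k)
    t_gamma = rng.random(shape) * x1[:, None]
    if literal_rho:
        t_rho = rng.beta(n0[:, None] + 1, n1[:, None] + 1, shape)
    else:
        t_rho = rng.beta(n1[:, None] + 1, n0[:, None] + 1, shape)
    v = rng.chisquare(np.broadcast_to((n1 - 1)[:, None], shape))
    t_sigma2 = (n1 - 1)[:, None] * s2_unb[:, None] / v
    w = rng.standard_normal(shape)
    t_mu = mu_hat[:, None] - w * np.sqrt(t_sigma2 / n1[:, None])
    t_eta = t_rho * (t_gamma + np.exp(t_mu))
    return {"gamma": t_gamma, "rho": t_rho, "mu": t_mu,
            "sigma2": t_sigma2, "eta": t_eta}


def mover_log_eta_bounds(gamma_hat, mu_hat, rho_hat, pivots, level):
    """Per-group MOVER bounds for ln(eta) from component percentile CIs.

    Component intervals: gamma from its uniform pivot draws, exp(mu) from the
    exponentiated mu-pivot percentiles, rho from the Beta pivot draws.  An
    inner root-sum-of-squared-margins step combines gamma and exp(mu) into
    bounds for ln(gamma + exp(mu)); an outer step adds the ln(rho) component.
    Returns (ln_eta_hat, lower, upper) arrays.
    """
    phi = 1.0 - level
    qlo, qhi = phi / 2, 1 - phi / 2
    gamma_hat = np.atleast_1d(np.asarray(gamma_hat, dtype=float))
    mu_hat = np.atleast_1d(np.asarray(mu_hat, dtype=float))
    rho_hat = np.atleast_1d(np.asarray(rho_hat, dtype=float))
    lg = np.quantile(pivots["gamma"], qlo, axis=1)
    ug = np.quantile(pivots["gamma"], qhi, axis=1)
    le = np.exp(np.quantile(pivots["mu"], qlo, axis=1))
    ue = np.exp(np.quantile(pivots["mu"], qhi, axis=1))
    lr = np.quantile(pivots["rho"], qlo, axis=1)
    ur = np.quantile(pivots["rho"], qhi, axis=1)
    emu = np.exp(mu_hat)
    a = gamma_hat + emu
    inner_lo = a - np.sqrt((gamma_hat - lg) ** 2 + (emu - le) ** 2)
    inner_hi = a + np.sqrt((ug - gamma_hat) ** 2 + (ue - emu) ** 2)
    if np.any(inner_lo <= 0):
        raise ValueError(
            "MOVER inner bound for gamma + exp(mu) is non-positive; "
            "log-scale combination undefined"
        )
    ln_a = np.log(a)
    ln_eta = np.log(rho_hat) + ln_a
    lo = ln_eta - np.sqrt((np.log(rho_hat) - np.log(lr)) ** 2
                          + (ln_a - np.log(inner_lo)) ** 2)
    hi = ln_eta + np.sqrt((np.log(ur) - np.log(rho_hat)) ** 2
                          + (np.log(inner_hi) - ln_a) ** 2)
    return ln_eta, lo, hi


def mover_combine_ratio(ln_eta1, lo1, hi1, ln_eta2, lo2, hi2):
    """Donner–Zou combination of two groups' ln(eta) bounds into a ratio CI."""
    d = ln_eta1 - ln_eta2
    lower = np.exp(d - np.sqrt((ln_eta1 - lo1) ** 2 + (hi2 - ln_eta2) ** 2))
    upper = np.exp(d + np.sqrt((hi1 - ln_eta1) ** 2 + (ln_eta2 - lo2) ** 2))
    return lower, upper


# ---------------------------------------------------------------------------
# normal-approximation components

def ms_median_variance(pos_sorted: np.ndarray, mask: np.ndarray,
                       n1: np.ndarray, *, literal_sum=False):
    """Distribution-free order-statistic variance of the sample median.

    ``c = floor((n1 + 1)/2 - 1.96 sqrt(n1/4))`` clamped to >= 1;
    ``v = ((X_(n1-c+1) - X_(c)) / (2 * 1.96))**2`` (spread form).  With
    ``literal_sum`` the two order statistics are added instead of
    subtracted, matching the printed formula symbol-for-symbol.
    Rows must be sorted ascending within the first n1 entries.
    """
    n1i = n1.astype(np.int64)
    c = np.floor((n1i + 1) / 2 - 1.96 * np.sqrt(n1i / 4.0)).astype(np.int64)
    c = np.maximum(c, 1)
    rows = np.arange(pos_sorted.shape[0])
    hi = pos_sorted[rows, n1i - c]       # X_(n1-c+1), 1-based
    lo = pos_sorted[rows, c - 1]         # X_(c)
    spread = hi + lo if literal_sum else hi - lo
    return (spread / (2 * 1.96)) ** 2, c


def na_log_eta_variance(gamma_hat, mu_hat, s2_unb, rho_hat, n, n1, v_ms,
                        *, include_rho_term=True):
    """Variance of ln(eta_hat): V^MS / E^2 plus the delta-method ln(rho) term."""
    e = gamma_hat + np.exp(mu_hat + s2_unb / (2 * n1))
    total = v_ms / e ** 2
    if include_rho_term:
        total = total + (1 - rho_hat) / (n * rho_hat)
    return total


# ---------------------------------------------------------------------------
# Bayesian posterior draws

def gamma_posterior_draws(rng, pos, mask, n1, mu_hat, s2_hat, k,
                          *, grid_points=512, cap=1 - 1e-6, chunk=64):
    """Draw gamma from its conditional posterior by normalized grid inversion.

    The unnormalized log-density (mu, sigma2 plugged in at their estimates) is
    ``-sum ln(x - g) - sum (ln(x - g) - mu)^2 / (2 s2)`` evaluated on
    ``grid_points`` equally spaced nodes over [0, cap * X_(1)).
    """
    b = pos.shape[0]
    x1 = np.where(mask, pos, np.inf).min(1)
    frac = np.linspace(0.0, cap, grid_points)
    out = np.empty((b, k))
    for s in range(0, b, chunk):
        sl = slice(s, min(s + chunk, b))
        gs = frac[None, :] * x1[sl, None]                      # (c, G)
        d = pos[sl, :, None] - gs[:, None, :]                  # (c, M, G)
        ld = np.where(mask[sl, :, None], np.log(np.where(
            mask[sl, :, None], d, 1.0)), 0.0)
        logd = (-ld.sum(1)
                - np.where(mask[sl, :, None],
                           (ld - mu_hat[sl, None, None]) ** 2, 0.0).sum(1)
                / (2 * s2_hat[sl, None]))
        logd -= logd.max(1, keepdims=True)
        w = np.exp(logd)
        cdf = np.cumsum(w, axis=1)
        tot = cdf[:, -1]
        if np.any(tot <= 0) or np.any(~np.isfinite(tot)):
            raise ValueError("degenerate gamma posterior on the grid")
        cdf /= tot[:, None]
        u = rng.random((sl.stop - sl.start, k))
        for i in range(cdf.shape[0]):
            out[s + i] = np.interp(u[i], cdf[i], gs[i])
    return out


def sigma2_mu_posterior_draws(rng, n1, mu_hat, s2_unb, k, *, plugin_mu=False):
    """Draw (sigma2, mu) from the normal-approximation posteriors.

    sigma2 ~ Normal(s2_tilde, 2 s2_tilde^2 / (n1 + 2)) truncated to > 0 by
    resampling, with ``s2_tilde = n1 s2_unb / (n1 + 2)``; mu | sigma2 ~
    Normal(mu_hat, sigma2 / n1) (or with the plug-in variance ``s2_unb / n1``
    when ``plugin_mu``).
    """
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    mu_hat = np.atleast_1d(np.asarray(mu_hat, dtype=float))
    s2_unb = np.atleast_1d(np.asarray(s2_unb, dtype=float))
    b = n1.size
    s2t = n1 * s2_unb / (n1 + 2)
    sd = np.sqrt(2 * s2t ** 2 / (n1 + 2))
    f_s2 = rng.normal(s2t[:, None], sd[:, None], (b, k))
    bad = f_s2 <= 0
    tries = 0
    while bad.any():
        f_s2[bad] = rng.normal(np.broadcast_to(s2t[:, None], (b, k))[bad],
                               np.broadcast_to(sd[:, None], (b, k))[bad])
        bad = f_s2 <= 0
        tries += 1
        if tries > 1000:
            raise ValueError("sigma2 posterior truncation failed to converge")
    var_mu = (s2_unb[:, None] if plugin_mu else f_s2) / n1[:, None]
    f_mu = rng.normal(mu_hat[:, None], np.sqrt(var_mu))
    return f_s2, f_mu


def rho_posterior_draws(rng, n0, n1, k, *, alpha=1.0, beta=1.0):
    """Beta(n1 + beta, n0 + alpha) posterior draws of the nonzero proportion."""
    n0 = np.atleast_1d(np.asarray(n0, dtype=float))
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    return rng.beta(n1[:, None] + beta, n0[:, None] + alpha,
                    (n0.size, k))


# ---------------------------------------------------------------------------
# percentile interval

def percentile_interval(draws: np.ndarray, level: float):
    """Equal-tailed empirical percentile interval along the last axis."""
    phi = 1.0 - level
    lo = np.quantile(draws, phi / 2, axis=-1)
    hi = np.quantile(draws, 1 - phi / 2, axis=-1)
    return lo, hi
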