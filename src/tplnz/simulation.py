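"""Monte Carlo evaluation harness for the four interval methods.

A :class:`Scenario` fixes the two group sizes, the zero percentages
``d = 100 (1 - rho)``, the thresholds, the common log-scale variance and the
log-scale locations (``mu = 1`` by default; the location does not alter the
ratio's sampling behaviour but is part of the generating conditions).  For
each replicate two TPLNZ samples are generated, each requested method's
interval is computed, and the run is summarised per method by

* CP — percentage of intervals covering the true ratio ``omega``;
* LEP / UEP — percentage of runs with ``omega`` below / above the interval;
* EL — mean interval length;
* RB — relative bias ``(UEP - LEP) / (UEP + LEP)``.

The true ``omega`` uses the same median functional the intervals target.
The whole replicate batch is vectorized; identical master seeds give
identical metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .bayes import BayesConfig
from .mle import AdamConfig

__all__ = [
    "Scenario",
    "PerfMetrics",
    "relative_bias",
    "study_scenarios",
    "evaluate_scenario",
    "metrics_frame",
    "METHODS",
]

METHODS = ("fiducial", "mover", "na", "bayes")

#: (n1, n2) pairs of the simulation grid, small to moderately large.
_SIZE_PAIRS = [(25, 25), (25, 50), (50, 50), (50, 100),
               (100, 100), (100, 200)]
#: (gamma1, gamma2) pairs.
_GAMMA_PAIRS = [(1.0, 1.0), (1.0, 3.0), (3.0, 5.0)]


@dataclass(frozen=True)
class Scenario:
    """One simulation condition for the two-group comparison."""

    scenario_id: int
    n1: int
    n2: int
    zero_pct1: float
    zero_pct2: float
    gamma1: float
    gamma2: float
    sigma2: float
    mu1: float = 1.0
    mu2: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.zero_pct1 < 100 and 0 < self.zero_pct2 < 100):
            raise ValueError("zero percentages must lie in (0, 100)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def rho1(self) -> float:
        return 1.0 - self.zero_pct1 / 100.0

    @property
    def rho2(self) -> float:
        return 1.0 - self.zero_pct2 / 100.0

    @property
    def true_omega(self) -> float:
        eta1 = self.rho1 * (self.gamma1 + np.exp(self.mu1))
        eta2 = self.rho2 * (self.gamma2 + np.exp(self.mu2))
        return eta1 / eta2


@dataclass(frozen=True)
class PerfMetrics:
    """Coverage and length summary of one method under one scenario."""

    cp: float
    lep: float
    uep: float
    el: float
    rb: float
    reps: int
    excluded: int = 0


def relative_bias(lep: float, uep: float) -> float:
    """Relative bias (UEP - LEP) / (UEP + LEP).

    Returns ``nan`` (the documented sentinel) when both error probabilities
    are zero, where the balance is undefined.
    """
    if lep < 0 or uep < 0:
        raise ValueError("error probabilities must be non-negative")
    if lep + uep == 0:
        return float("nan")
    return (uep - lep) / (uep + lep)


def study_scenarios() -> list[Scenario]:
    """The 72 tabulated scenarios of the two simulation studies.

    Study 1 (ids 1-36): zero-percentage pairs (10, 10) and (10, 30) with
    ``sigma2 = 1.25``.  Study 2 (ids 37-72): pairs (20, 40) and (40, 40)
    with ``sigma2 = 3``.  Both cross six size pairs with three threshold
    pairs; ``mu = 1`` is attached to every scenario.
    """
    out = []
    sid = 1
    for sigma2, zero_pairs in ((1.25, [(10.0, 10.0), (10.0, 30.0)]),
                               (3.0, [(20.0, 40.0), (40.0, 40.0)])):
        for n_pair in _SIZE_PAIRS:
            for d_pair in zero_pairs:
                for g_pair in _GAMMA_PAIRS:
                    out.append(Scenario(
                        scenario_id=sid, n1=n_pair[0], n2=n_pair[1],
                        zero_pct1=d_pair[0], zero_pct2=d_pair[1],
                        gamma1=g_pair[0], gamma2=g_pair[1], sigma2=sigma2))
                    sid += 1
    return out


def _generate_group(rng, reps, n, rho, gamma, mu, sigma2):
    """Padded positives, counts and mask for `reps` samples of one group."""
    nonzero = rng.random((reps, n)) < rho
    n1 = nonzero.sum(1)
    raw = gamma + np.exp(rng.normal(mu, np.sqrt(sigma2), (reps, n)))
    m = int(n1.max())
    pad = float(raw.max()) * 2 + 1
    order = np.argsort(~nonzero, axis=1, kind="stable")  # nonzero first
    pos = np.take_along_axis(np.where(nonzero, raw, pad), order, axis=1)[:, :m]
    mask = np.arange(m)[None, :] < n1[:, None]
    return pos, n1.astype(float), n - n1, mask


def _group_arrays(rng, scenario, gi, reps, adam_cfg, min_n1):
    n = scenario.n1 if gi == 0 else scenario.n2
    rho = scenario.rho1 if gi == 0 else scenario.rho2
    gamma = scenario.gamma1 if gi == 0 else scenario.gamma2
    mu = scenario.mu1 if gi == 0 else scenario.mu2
    pos, n1, n0, mask = _generate_group(rng, reps, n, rho, gamma, mu,
                                        scenario.sigma2)
    ok = n1 >= min_n1
    gam, _, _ = _engine.adam_threshold(
        pos, mask, np.maximum(n1, 2),
        beta1=adam_cfg.beta1, beta2=adam_cfg.beta2,
        epsilon=adam_cfg.epsilon, step_size=adam_cfg.step_size,
        max_iter=adam_cfg.max_iter, grad_tol=adam_cfg.grad_tol,
        cap=adam_cfg.gamma_cap_fraction, u0=adam_cfg.gamma0_fraction,
        printed=(adam_cfg.objective == "printed"))
    mu_hat, _, s2u = _engine.log_moments(pos, mask, np.maximum(n1, 2), gam)
    x1 = np.where(mask, pos, np.inf).min(1)
    return {"pos": pos, "mask": mask, "n": n, "n1": n1, "n0": n0,
            "gam": gam, "mu": mu_hat, "s2u": s2u, "x1": x1,
            "rho": n1 / n, "ok": ok}


def evaluate_scenario(scenario: Scenario, methods=METHODS, reps: int = 5000,
                      level: float = 0.95, k: int = 2500,
                      adam_cfg: AdamConfig | None = None,
                      bayes_cfg: BayesConfig | None = None,
                      seed=None) -> dict[str, PerfMetrics]:
    """Monte Carlo performance of the requested methods under one scenario.

    Replicates whose estimation is infeasible (fewer than 5 positive values)
    are excluded and counted; the run aborts if they exceed 1% of ``reps``.
    The fiducial and MOVER intervals are built from the same pivot draws
    (one Monte Carlo pass per replicate, as in a shared sampling pass).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    adam_cfg = adam_cfg or AdamConfig()
    bayes_cfg = bayes_cfg or BayesConfig()
    ss = np.random.SeedSequence(seed)
    rng_gen, rng_piv, rng_bay = [np.random.default_rng(s)
                                 for s in ss.spawn(3)]
    groups = [_group_arrays(rng_gen, scenario, gi, reps, adam_cfg, 5)
              for gi in range(2)]
    ok = groups[0]["ok"] & groups[1]["ok"]
    excluded = int(reps - ok.sum())
    if excluded > 0.01 * reps:
        raise RuntimeError(
            f"{excluded} of {reps} replicates infeasible (>1%); "
            "scenario too extreme for these sample sizes")
    omega = scenario.true_omega
    out: dict[str, PerfMetrics] = {}

    def metrics(lo, hi):
        lo, hi = lo[ok], hi[ok]
        covered = (lo <= omega) & (omega <= hi)
        lep = 100.0 * np.mean(omega < lo)
        uep = 100.0 * np.mean(omega > hi)
        return PerfMetrics(
            cp=100.0 * np.mean(covered), lep=lep, uep=uep,
            el=float(np.mean(hi - lo)), rb=relative_bias(lep, uep),
            reps=int(ok.sum()), excluded=excluded)

    if "fiducial" in methods or "mover" in methods:
        piv = [_engine.fiducial_pivots(rng_piv, g["x1"], g["n0"], g["n1"],
                                       g["mu"], g["s2u"], k)
               for g in groups]
        if "fiducial" in methods:
            lo, hi = _engine.percentile_interval(
                piv[0]["eta"] / piv[1]["eta"], level)
            out["fiducial"] = metrics(lo, hi)
        if "mover" in methods:
            bounds = [_engine.mover_log_eta_bounds(
                g["gam"], g["mu"], g["rho"], p, level)
                for g, p in zip(groups, piv)]
            lo, hi = _engine.mover_combine_ratio(*bounds[0], *bounds[1])
            out["mover"] = metrics(lo, hi)
    if "na" in methods:
        z = stats.norm.ppf(1 - (1 - level) / 2)
        var = []
        for g in groups:
            v_ms, _ = _engine.ms_median_variance(
                g["pos"], g["mask"], np.maximum(g["n1"], 2))
            var.append(_engine.na_log_eta_variance(
                g["gam"], g["mu"], g["s2u"], np.clip(g["rho"], 1e-12, None),
                g["n"], np.maximum(g["n1"], 2), v_ms))
        d = (np.log(groups[0]["rho"] * (groups[0]["gam"]
                                        + np.exp(groups[0]["mu"])))
             - np.log(groups[1]["rho"] * (groups[1]["gam"]
                                          + np.exp(groups[1]["mu"]))))
        margin = z * np.sqrt(var[0] + var[1])
        out["na"] = metrics(np.exp(d - margin), np.exp(d + margin))
    if "bayes" in methods:
        etas = []
        for g in groups:
            f_g = _engine.gamma_posterior_draws(
                rng_bay, g["pos"], g["mask"], np.maximum(g["n1"], 2),
                g["mu"], g["s2u"], bayes_cfg.k if k is None else k,
                grid_points=bayes_cfg.gamma_grid_points)
            f_r = _engine.rho_posterior_draws(
                rng_bay, g["n0"], g["n1"], f_g.shape[1],
                alpha=bayes_cfg.alpha_prior, beta=bayes_cfg.beta_prior)
            f_s2, f_mu = _engine.sigma2_mu_posterior_draws(
                rng_bay, np.maximum(g["n1"], 2), g["mu"], g["s2u"],
                f_g.shape[1], plugin_mu=bayes_cfg.mu_plugin_sigma)
            etas.append(f_r * (f_g + np.exp(f_mu)))
        lo, hi = _engine.percentile_interval(etas[0] / etas[1], level)
        out["bayes"] = metrics(lo, hi)
    return out


def metrics_frame(results: dict[int, dict[str, PerfMetrics]]) -> pd.DataFrame:
    """Tidy frame of {scenario_id: {method: PerfMetrics}} results."""
    rows = []
    for sid, per_method in results.items():
        for method, m in per_method.items():
            rows.append({"scenario_id": sid, "method": method, "cp": m.cp,
                         "lep": m.lep, "uep": m.uep, "el": m.el, "rb": m.rb,
                         "reps": m.reps, "excluded": m.excluded})
    return pd.DataFrame(rows)
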