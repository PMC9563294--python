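# Methods

## Model

An observation from a zero-inflated three-parameter lognormal (TPLNZ)
population is exactly zero with probability `1 − ρ` and otherwise equals
`γ + exp(Z)` with `Z ~ N(μ, σ²)`.  The density is `1 − ρ` at zero, zero on
`(0, γ]`, and the `ρ`-weighted lognormal density of `x − γ` above the
threshold.  "Zero" means exactly `0.0`: the model places an atom there, so
no tolerance band is applied.

The estimand is the median functional `η = ρ[γ + exp(μ)]` — the nonzero
probability times the median of the positive part — and, for two
independent populations, `ω = η₁/η₂`.  `η` is *not* the quantile of the
mixture distribution (that would be a different, less tractable target);
every interval in the package and the truth used by the simulation harness
target the same functional, so coverage is internally consistent.

## Threshold estimation

Given `γ`, the other maximum-likelihood estimates are closed-form:
`μ̂ = mean ln(x − γ)`, `σ̂²` with divisor `n₁` (MLE) or `n₁ − 1` (unbiased),
`ρ̂ = n₁/n`.  Wherever a formula writes `σ̂²` without qualification the
unbiased divisor is meant; the MLE divisor is only used where explicitly
named.

`γ` itself is estimated by an adaptive-moment (Adam) gradient iteration on
the normalized coordinate `u = γ/X₍₁₎` (`X₍₁₎` is the smallest positive
observation), which makes the step size scale-free.  Defaults:
`β₁ = 0.9`, `β₂ = 0.999`, `ε = 1e−8`, step `δ = 0.01` (in `X₍₁₎` units),
start `u₀ = 0.5`, at most 5000 iterations, stop when the scaled gradient
falls below `1e−6`, feasible box `[0, (1 − 1e−6)·X₍₁₎]`.  The update fed to
the standard subtract-the-step Adam rule is the *negative* of the
objective's γ-derivative, so the iteration ascends.

Two objectives are provided because the threshold likelihood admits two
materially different readings:

* **`objective="printed"` (default).**  The γ-derivative of the likelihood
  written with a positive `n₁/2` power on `2πσ²`.  Its profile in `γ`
  increases monotonically toward `X₍₁₎` for every dataset, so the iteration
  climbs until the next step would leave the support and returns the last
  feasible iterate — one Adam step below the sample minimum.  This is the
  variant whose behaviour matches the published wind-speed parameter
  estimates and interval lengths, as well as the published simulation
  behaviour (strongly conservative fiducial coverage driven by the inflated
  `σ̂²` that a near-minimum threshold induces), and it is therefore the
  default for interval estimation.  Lower-bound violations are projected to
  0; an upper-cap proposal stops the row because the objective is monotone
  there and every later iterate would merely sit at the cap with a
  degenerate log term.
* **`objective="profile"`.**  The canonical profile score
  `Σ 1/(x−γ) + (n₁/S) Σ dev/(x−γ)` (with `dev = ln(x−γ) − mean`,
  `S = Σ dev²`), i.e. the derivative of the correctly signed profile
  log-likelihood.  On data generated with an interior threshold this has a
  stationary point near the truth, and the iteration converges to it; cap
  violations are projected back and iteration continues, since the score is
  negative at the cap and pushes the iterate down.  Because fixed-step Adam
  settles only to within about one step of the root, the final iterate is
  polished by bracketed bisection of the score over a one-step
  neighbourhood (machine-precision root, start-point independent).  This is
  the textbook local MLE and is used wherever a maximized likelihood is
  required — in particular the AIC comparison, where the printed-objective
  iterate would not be a likelihood maximizer and its "AIC" would be
  meaningless.

The profile log-likelihood of a threshold model is formally unbounded as
`γ → X₍₁₎`, but the divergence only manifests at standoffs around
`e^{-n₁}`, far below anything the iteration visits; within the feasible box
both objectives are numerically benign.

## Fiducial and MOVER intervals

Pivots per fitted sample: `T_γ ~ Uniform(0, X₍₁₎)`;
`T_ρ ~ Beta(n₁+1, n₀+1)` (the *nonzero*-proportion pivot — the complement
of the zero-proportion Beta pivot — because `η` multiplies by `ρ`; the
literal zero-proportion multiplier is available behind
`pivot_rho_literal` for comparison); `T_σ² = (n₁−1)s²/V`, `V ~ χ²(n₁−1)`,
where `s²` must be the unbiased *variance* of `ln(x − γ̂)` (a first-moment
reading would allow negative `T_σ²` and an undefined `T_μ`);
`T_μ = μ̂ − W√(T_σ²/n₁)`, `W` standard normal.  `T_η = T_ρ(T_γ + e^{T_μ})`
and `T_ω = T_η₁/T_η₂`; the interval is the equal-tailed pair of empirical
percentiles (numpy's linear-interpolation quantile convention, fixed
throughout) of `K = 2500` draws by default.

The MOVER variant forms per-component percentile intervals — `γ` from the
uniform pivot draws, `exp(μ)` from exponentiated `T_μ` percentiles, `ρ`
from the Beta pivot draws — then applies the canonical root-sum-of-squared-
margins combination twice per group (inner: `ln[γ + exp(μ)]`; outer: adding
the `ln ρ` component) and once across groups for the log-ratio.  All
combinations use each component's own `(lower, upper)` pair; a component
interval that collapses to a point contributes a zero margin.  If an inner
bound for `γ + exp(μ)` is non-positive the log combination is undefined and
an error names the offending component.

## Normal-approximation interval

`Var(ln η̂)` is estimated as `V^MS/E² + (1 − ρ̂)/(n ρ̂)` where
`V^MS = [(X₍n₁−c+1₎ − X₍c₎)/(2·1.96)]²` with
`c = max(1, floor((n₁+1)/2 − 1.96√(n₁/4)))` computed on the positives only
(the statistic indexes a sample of size `n₁`), and
`E = γ̂ + exp(μ̂ + σ̂²/(2n₁))`.  The order statistics enter as a *spread*:
the additive form is not location-invariant and explodes for shifted data
(it is kept behind `literal_sum` for comparison).  The `ln ρ̂` term is
included by default because `ln η = ln ρ + ln[γ + exp(μ)]` and the
zero-inflation uncertainty would otherwise be ignored; `include_rho_term`
disables it.  A sample with no zeros takes the `ρ̂ = 1` limit (the term
vanishes).  The interval is `exp[(ln η̂₁ − ln η̂₂) ∓ z_{1−φ/2}√(V₁+V₂)]` —
deterministic given the fits.  Its simulated mean length can be inflated by
rare replicates with extreme margins (the exponential map amplifies them);
the harness reports the mean, which is what makes the NA method's expected
length the longest of the four.

## Bayesian interval

Under a `Beta(α, β)` prior on the nonzero proportion (uniform `α = β = 1`
by default), `ρ | data ~ Beta(n₁+β, n₀+α)`.  The threshold's conditional
posterior (location and scale plugged at their estimates) is sampled by
normalized grid inversion over `[0, (1−1e−6)X₍₁₎]` with 512 equally spaced
nodes by default; the normalizing constant is absorbed by the grid
normalization, draws interpolate the inverse CDF, and refinement to 4096
nodes moves the posterior mean by less than `1e−3·X₍₁₎` on moderate
samples.  `σ²` is drawn from the normal approximation centred at
`σ̃² = n₁σ̂²/(n₁+2)` with variance `2σ̃⁴/(n₁+2)`, truncated to positive
values by resampling (the approximation can put mass below zero; truncation
preserves its shape on the valid domain).  `μ | σ²` is
`N(μ̂, σ²/n₁)`, hierarchically over the `σ²` draws by default; the strict
plug-in variance `σ̂²/n₁` is available via `mu_plugin_sigma`.  `σ²` enters
the ratio only through the `μ` posterior — `η` has no `σ²` term.  The
credible interval is the equal-tailed percentile pair of
`f_ρ(f_γ + e^{f_μ})` ratio draws.

## Monte Carlo harness

`study_scenarios()` returns the 72 tabulated conditions: six size pairs
(25, 25) … (100, 200) × three threshold pairs (1, 1), (1, 3), (3, 5) ×
zero-percentage pairs (10, 10)/(10, 30) at `σ² = 1.25` (ids 1–36) and
(20, 40)/(40, 40) at `σ² = 3` (ids 37–72).  The tabulated design lists
*zero* percentages; the generator uses `ρ = 1 − d/100`.  The log-scale
location is not part of the tabulated design; the package fixes `μ = 1`
in both groups as its default generating condition (the ratio interval is
scale-free, so this choice affects lengths only through the `γ`-to-`e^μ`
balance), exposed per scenario for sensitivity checks.

`evaluate_scenario` vectorizes all replicates of a scenario through the
same kernels the per-sample API uses (padded arrays, one batch row per
replicate), which is what keeps 1000-replicate runs in seconds on one
core.  Replicate streams derive from the master seed via `SeedSequence`
spawning; identical seeds give identical metrics.  Replicates with fewer
than five positive observations are excluded and counted, and the run
aborts if they exceed 1% (they essentially never occur at the tabulated
sizes).  The fiducial and MOVER intervals share one pivot pass per
replicate.  "Expected length" is the mean of the interval lengths.
Default full-scale settings are 5000 replicates × 2500 draws; the
acceptance checks and examples run desk-scale versions (500–1000
replicates, 500 draws), which the package treats as its standard
reduced-replication problem sizes.

## What the generator does and does not emulate

`tplnz_rng` draws exact zeros with probability `1 − ρ` and shifted
lognormal positives — precisely the model the intervals assume.  Real
wind-speed series violate this in ways the synthetic study cannot expose:
serial correlation between consecutive hours, measurement rounding (the
packaged data are recorded to 0.1 km/3h, so "zero" means below the
instrument's resolution rather than a true atom), and seasonal
non-stationarity.  Passing coverage tests therefore certify the methods
*under the model*, not robustness to these departures.

## Known limitations

* The printed-objective threshold estimate is a boundary iterate, not a
  stationary point; its standoff below `X₍₁₎` (hence the fitted `σ̂²`)
  depends on the step size.  This is intrinsic to the reconstructed
  estimator; the profile objective is provided for users who want the
  canonical local MLE.
* The Bayesian `σ²` posterior is a normal approximation; for very small
  `n₁` its truncation bias grows and a warning-level rejection cap guards
  pathological cases.
* The NA method's mean simulated length is outlier-dominated at small
  sizes; the median length would be far smaller, but the mean is the
  conventional summary and is what the harness reports.
* One-sided intervals, censored observations and the mixture's true
  distributional median are out of scope.
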