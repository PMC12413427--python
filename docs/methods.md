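# Methods

## Model

`mlmvar` implements multilevel vector-autoregressive (VAR(1)) models for
intensive longitudinal data in which the dynamics operate on latent,
person-mean-centered states and may include *within-level latent
interaction* (moderation) terms.

Observed indicators decompose into a stable person component and a
time-specific deviation,

    Y_it = mu_i + Y^w_it,

with optional measurement models on both levels,

    Y^w_it = Lambda_W eta^w_it + eps^w_it,
    mu_i   = alpha + Lambda_B eta^mu_i + eps^B_i.

Single-indicator constructs set the loadings to 1 and omit the error
terms, so the within-level state equals the centered observation.  The
within-person dynamics of the `Q <= 3` latent states are

    eta^w_qit = sum_j phi_j(i) x_jit + zeta_qit,

where each regressor `x_j` is a lagged state (AR when outcome equals
predictor, CR otherwise), a same-occasion state (lag 0, allowed when the
resulting same-time graph is acyclic), or a pairwise product of two
(possibly differently lagged) states — the latent interaction terms.
Innovations `zeta_it` are multivariate normal within occasions and
serially uncorrelated.

All trait means are person-specific.  In random-effects variants the phi
coefficients and the log innovation variances are person-specific too,
jointly multivariate normal at the between level with means (fixed
effects) `gamma`, scales `tau`, and a full correlation matrix.
Person-specific innovation *covariances* use the common-factor
construction: `zeta_q = c_q eta_zeta + delta_q` with log-normally
distributed variance components, which keeps every implied covariance
matrix positive definite while letting the covariance vary across
persons; the sign pattern `c` is a model-level constant (default
positive).

## Priors

Weakly informative and admissible-range oriented, suited to observed
values in a 0–10 range: trait means Normal(0, 4²); dynamic coefficients
Normal(0, 1); trait scales half-Cauchy(0, 1); random-effect scales of phi
coefficients half-Cauchy(0, 0.5); innovation SDs half-Cauchy(0, 1); fixed
effects of log innovation variances Normal(0, 1) with half-Cauchy(0, 1)
scales; LKJ(1) on Cholesky factors of all correlation matrices; loadings
Normal(1, 0.5²); intercepts Normal(0, 10²); measurement error SDs
half-Cauchy(0, 1).  Data on a very different scale should be rescaled or
the trait priors adjusted.

## Posterior computation

Scales are sampled on the log scale; correlation matrices through the
canonical-partial-correlation Cholesky transform.  All person-varying
effects are non-centered: the sampler works on standard-normal person
vectors `z_i` with `effects_i = gamma + diag(tau) L z_i`.  Latent states
of multiple-indicator constructs are free parameters, as are states at
missing occasions of single-indicator constructs — missing beeps are
handled inside the MCMC, and lagged terms are skipped wherever
`lag_valid` is false (overnight gaps, wave boundaries, the first
occasion).  States that open a day/wave segment receive a
diffuse-stationary prior: a mean-zero normal with the covariance implied
by the linearized dynamics (interactions evaluated at zero moderator);
parameter draws whose linearized transition matrix is non-stationary get
zero posterior mass, consistent with the local-stationarity assumption of
the model.  A `conditional` mode that simply drops these initial-state
terms is available.

The sampler is a blocked adaptive Metropolis-within-Gibbs scheme written
for this package:

* adaptive random-walk Metropolis on global sub-blocks (dynamic +
  innovation parameters, twice per iteration; between-level
  hyperparameters; measurement parameters), with the proposal covariance
  estimated during warm-up (Haario-style) and Robbins–Monro scale
  adaptation;
* ancillarity-sufficiency interweaving moves for every person-effect
  location (`gamma`), scale (`tau`) and for the between-level correlation
  matrix: the hyperparameter moves while the person vectors are adjusted
  to keep the realized effects fixed (with the appropriate Jacobian), so
  the acceptance depends only on prior terms.  These moves remove the
  strong coupling between hyperparameters and the data-dominated person
  effects that cripples plain random-walk updates;
* one parallel update of all person vectors (conditionally independent
  given the globals), with per-person adapted step sizes;
* a sequential-in-time Metropolis sweep over free latent states with
  per-cell accept/reject based on the local measurement, dynamic and
  initial-state terms.

All adaptation runs during the first 50% of iterations (warm-up,
discarded) and is frozen afterwards.  Defaults follow the simulation
protocol: 2 chains, 4,000 iterations each, 50% warm-up.  Because the
sampler is not Hamiltonian there are no divergent transitions;
`n_divergent` is always reported as zero and convergence assessment
leans on split-Rhat and bulk/tail ESS (computed with the rank-normalized
estimators in `arviz`).

Convergence verdicts: *strict* = all Rhat < 1.01, minimum bulk and tail
ESS > 100 per chain, no divergences; *lenient* = Rhat < 1.05 only.  A
strictly non-converged fit is rerun exactly once with twice the
iterations and a new deterministically derived seed (the rerun-seed
choice is this package's; retaining the original seed would reproduce the
identical chain), then flagged excluded if still failing.

## Synthetic data

The generator mirrors the estimation model.  Person parameters are drawn
from the between-level multivariate normal and rejection-resampled until
they pass a local-stationarity screen: every AR coefficient inside
(−1, 1), linearized spectral radius below 1, and a screening simulation
of the person's series staying finite within a configurable bound
(default 10³) — the screen is this package's concrete test for the
qualitative requirement of locally stationary trajectories in the
presence of interaction terms.  Series start at zero and discard a
500-step burn-in by default.

Default generating values are the canonical study conditions: AR fixed
effects 0.3–0.4, CR magnitudes 0.1–0.25, interaction magnitudes
0.05–0.2 (e.g. Model A: `phi_11 = 0.35`, `phi_21 = 0.15`, `phi_22 = 0.3`,
`phi_2.12 = 0.1`); random-effect variances of phi coefficients 0.01; log
innovation variances −0.5 (or −0.7 plus a common factor at −1.3 when the
innovation covariance is random) with random-effect variance 0.2; factor
loadings 1 with within-level error variance 0.3 (mean item reliability
about .72); trait correlation 0.3; trait means 5 with SDs 0.8
(single-indicator) / 0.95 (factor), which keep observations in a 0–10
range at intra-class correlations of 0.4–0.5.  Between-level measurement
error variances default to zero (matching the simulated study
conditions); item-specific stable residual traits can be switched on for
empirical-style factor models.

What the generator does *not* emulate: non-equidistant sampling times,
trends or cycles, non-Gaussian innovations, floor/ceiling effects of
rating scales, and planned-missingness designs beyond uniform
missing-at-random masking and day/wave grids.  Passing recovery tests on
these data therefore demonstrate correctness of the estimator under the
model, not robustness to real-data violations of it.

## Recovery harness

Each condition simulates replicated datasets, fits with the rerun
protocol, and scores per parameter: relative bias (mean posterior mean /
truth; adequate in 0.9–1.1), 95% coverage (adequate above 0.91), MSE, and
power (95% CI excluding zero; adequate above 0.8).  Metrics are reported
under both the strict and lenient convergence regimes; replication seeds
derive deterministically from the condition seed base.

The default harness scale is reduced — around 20 replications per
condition at N = 25 persons and T = 25–50 occasions, the scale used by
`scripts/acceptance.py` — with larger grids reachable through the
configuration.  At this scale the Monte-Carlo noise floor matters: with
20 replications the standard error of a relative-bias estimate for a
coefficient of 0.1 is roughly 0.07, and coverage moves in steps of 0.05,
so the suite pools coverage across conditions and reads bias where the
sample supports it.  With the deliberately small generating interaction
(0.1), recovery at T = 25 is accurate for the main effects and
innovation SDs while the interaction coefficient is attenuated and
low-powered; at T = 50 every within-level parameter recovers inside the
10% band and interaction power is adequate.  The between-level
correlation needs larger N.  This ordering — short series suffice for
medium-sized effects only, small moderation effects need N or T to grow
— is the expected behavior for these models.

## Reporting layer

Within-person standardization multiplies each coefficient by the ratio of
the model-implied within-person SD of its regressor to the SD of its
outcome state.  AR effects are invariant (the two SDs coincide); CR
effects use the two state SDs; interaction terms use the SD of the
product regressor.  Interaction models have no closed-form stationary
moments, so implied SDs come from a forward simulation of the recursion,
vectorized across posterior draws with common random numbers (default
10⁵ retained steps, fixed internal seed; draws with non-finite moments
are excluded and counted).  Interaction-free models use the closed-form
VAR(1) stationary covariance.  Random-effects models standardize per
person — thinned to at most 200 draws by default, since the simulation
batch is draws × persons — then average across persons.

Simple-slope surfaces evaluate, per draw, `slope(m) = CR + interaction ×
m` at chosen standardized moderator values (default −1/0/+1 SD) over a
predictor range (default ±2.5 SD), optionally adding the AR term at a
fixed previous outcome level; the region of significance reports the
moderator values at which the 2.5%/97.5% quantile band of the slope
starts or stops covering zero (quantile-based across draws, with linear
interpolation at the crossing — not an analytic Johnson–Neyman boundary).
Within-level variance explained is `1 − Var(innovation)/Var(state)` per
draw; item reliabilities are `lambda² Var(eta^w) / (lambda² Var(eta^w) +
theta_w)`.

## Numerical choices and limitations

* The stationarity screen's trajectory bound (10³) and the linearized
  initial-state prior are pragmatic surrogates for conditions that have
  no exact finite test for moderated recursions; both are configurable.
* The initial-state prior uses the linearized stationary covariance,
  which understates the marginal variance of strongly moderated states;
  with day-based designs this affects one occasion per day segment.
* Relative bias is undefined at zero truths; absolute bias is reported
  and power skipped there.
* The sampler's random-walk core needs the full 4,000-iteration protocol
  for strict convergence on small datasets; very short chains will fail
  the strict criterion and trigger reruns.
* Model-fit indices (WAIC/LOO), latent-class/regime-switching structure,
  between-level interactions, lags beyond 1, more than three constructs,
  and continuous-time treatment of irregular intervals are out of scope.
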