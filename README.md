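# mlmvar

Multilevel latent moderated vector-autoregressive models for intensive
longitudinal data (experience sampling, ambulatory assessment).

## What problem this solves

Many questions about within-person processes — does mindful attention
weaken the link between rumination and subsequent negative affect? does
negative affect feed back on itself more strongly when rumination is
high? — are questions about *interactions between latent states* in a
person's moment-to-moment dynamics.  `mlmvar` implements multilevel
VAR(1) models in which observed indicators are decomposed by latent
person-mean centering,

    Y_it = mu_i + Y^w_it,      Y^w_it = Lambda_W eta^w_it + eps^w_it,

and the within-person latent states follow a moderated VAR(1), e.g. for
two constructs

    eta1_it = phi_11 eta1_i(t-1) + zeta1_it
    eta2_it = phi_21 eta1_i(t-1) + phi_22 eta2_i(t-1)
              + phi_2.12 (eta1_i(t-1) * eta2_i(t-1)) + zeta2_it,

with innovations `zeta ~ MVN(0, Sigma_zeta)`.  Latent centering avoids
the bias of observed person-mean centering, and the measurement model
controls for unreliability of the indicators.  AR, CR and interaction
coefficients and the innovation (co)variances can be fixed or
person-specific (random effects, jointly multivariate normal at the
between level; person-specific innovation covariances via a common-factor
construction with log-normal components).

The package is aimed at quantitative behavioral researchers who want to

* **simulate** realistic multilevel ILD with latent interactions
  (`mlmvar.simulate`),
* **fit** the model variants by Bayesian MCMC (`mlmvar.posterior`), with
  the convergence criteria and rerun protocol used in simulation practice
  (`mlmvar.diagnostics`),
* **evaluate** estimator performance over condition grids — relative
  bias, coverage, MSE, power (`mlmvar.simstudy`),
* **report** results: within-person standardized coefficients,
  interaction plots, regions of significance, variance explained, item
  reliabilities, random-effect distributions (`mlmvar.postprocess`),
* **prepare** beep-level data: occasion grids, missing-beep insertion,
  overnight/wave lag breaks (`mlmvar.io`).

See `docs/methods.md` for the model, priors, sampler and design choices.

## Worked example

```python
import numpy as np
import mlmvar as m

spec = m.build_model("A")                 # 2 constructs, 1 interaction
cfg = m.default_gen_config(spec, n_persons=25, n_times=50)
panel = m.simulate_dataset(cfg, spec, rng=np.random.default_rng(7))

draws = m.fit(spec, None, panel, chains=2, iterations=4000, seed=3)
print(draws.summary().round(3))
```

which prints (posterior means, 95% CI bounds, diagnostics):

```
                 mean   q2.5  q97.5   rhat  ess_bulk  ess_tail
parameter
phi_11          0.358  0.305  0.411  1.001   600.563  1021.839
phi_21          0.192  0.139  0.249  1.002   462.667   643.970
phi_22          0.285  0.228  0.341  1.003   480.232   678.899
phi_2.12        0.100  0.034  0.163  1.005   493.092   918.140
sigma_zeta_1    0.803  0.773  0.835  1.002   552.370  1050.257
sigma_zeta_2    0.774  0.746  0.804  1.001   600.434  1136.719
gamma_mu_1      4.905  4.605  5.200  1.004   666.767   864.055
gamma_mu_2      4.926  4.518  5.305  1.005   705.655   702.497
tau_mu_1        0.707  0.522  0.961  1.010   637.664   853.501
tau_mu_2        0.948  0.711  1.314  1.004   656.080   880.570
rho(mu_1,mu_2)  0.149 -0.239  0.510  1.003   591.354  1052.243
```

The generating values were `phi_11 = 0.35`, `phi_21 = 0.15`,
`phi_22 = 0.3`, `phi_2.12 = 0.1`, innovation SDs `exp(-0.25) = 0.779`,
trait means 5 with SD 0.8 and correlation 0.3: every 95% interval covers
its generating value, and the interaction effect (`phi_2.12`) is
credibly positive — previous levels of construct 1 amplify the carryover
of construct 2.  Post-processing continues with

```python
std = m.standardize(draws, spec)          # within-person standardized
surf = m.simple_slopes(std, spec)         # slopes at moderator -1/0/+1 SD
roi = m.region_of_significance(std, spec) # where the slope CI excludes 0
```

A thin CLI mirrors the main steps: `mlmvar simulate`, `mlmvar fit`,
`mlmvar gridify`, `mlmvar simstudy` (see `--help`).

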