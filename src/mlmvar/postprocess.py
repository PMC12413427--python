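"""Reporting layer: within-person standardization and derived summaries.

Standardized dynamic coefficients rescale each effect by the ratio of the
model-implied within-person SD of its regressor to the SD of its outcome
state.  AR effects are invariant under this operation (predictor and
outcome share the same SD); CR effects use the two state SDs; interaction
effects use the SD of the product regressor.  For interaction models the
implied moments have no closed form and are obtained from a per-draw
forward simulation of the within-person recursion (vectorized across
draws, common random numbers); interaction-free models use the
closed-form VAR(1) stationary covariance.  In random-effects models
coefficients are standardized per person and then averaged across
persons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynamics
from .errors import ConfigurationError, EstimationError
from .modelspec import ModelSpec
from .posterior import PosteriorDraws

__all__ = [
    "StandardizedDraws",
    "InteractionSurface",
    "standardize",
    "simple_slopes",
    "region_of_significance",
    "variance_explained",
    "item_reliability",
    "random_effect_summaries",
]


@dataclass
class StandardizedDraws:
    """Per-draw standardized dynamic coefficients.

    ``coefs`` has shape (draws, n_terms); for random-effects models these
    are person-averages and ``person_coefs`` (draws, N, n_terms) holds the
    person-specific values.  ``state_sd`` / ``innovation_var`` carry the
    implied within-person moments used, enabling downstream summaries.
    ``n_excluded`` counts draws flagged non-stationary (non-finite implied
    moments) and dropped.
    """

    term_labels: list
    coefs: np.ndarray
    unstandardized: np.ndarray
    state_sd: np.ndarray
    innovation_var: np.ndarray
    person_coefs: np.ndarray | None = None
    n_excluded: int = 0

    def summary(self) -> pd.DataFrame:
        lo, hi = np.quantile(self.coefs, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "estimate": self.unstandardized.mean(axis=0),
                "std_est": self.coefs.mean(axis=0),
                "std_q2.5": lo,
                "std_q97.5": hi,
            },
            index=pd.Index(self.term_labels, name="term"),
        )


def _corr_matrix_from_pairs(pairs: np.ndarray, d: int) -> np.ndarray:
    R = np.eye(d)
    k = 0
    for i in range(1, d):
        for j in range(i):
            R[i, j] = R[j, i] = pairs[k]
            k += 1
    return R


def _fixed_effect_batches(draws: PosteriorDraws, spec: ModelSpec):
    """Per-draw phi (S, terms) and innovation covariance (S, Q, Q)."""
    flat = draws.flat()
    names = draws.names
    idx = {nm: i for i, nm in enumerate(names)}
    S = flat.shape[0]
    Q = spec.n_constructs
    phi = np.stack([flat[:, idx[t.label]] for t in spec.terms], axis=1)
    if spec.random_innovation_variances:
        ln_d = np.stack(
            [flat[:, idx[f"gamma_ln_sigma2_delta_{q + 1}"]] for q in range(Q)], axis=1
        )
        if spec.innovation_covariance == "random":
            cov = dynamics.common_factor_cov(
                ln_d, flat[:, idx["gamma_ln_sigma2_etazeta"]],
                spec.innovation_covariance_sign,
            )
        else:
            cov = np.zeros((S, Q, Q))
            cov[:, np.arange(Q), np.arange(Q)] = np.exp(ln_d)
    else:
        sig = np.stack([flat[:, idx[f"sigma_zeta_{q + 1}"]] for q in range(Q)], axis=1)
        cov = np.zeros((S, Q, Q))
        cov[:, np.arange(Q), np.arange(Q)] = sig**2
        if spec.innovation_covariance == "fixed" and Q > 1:
            pair_names = [
                f"rho(zeta_{j + 1},zeta_{i + 1})" for i in range(1, Q) for j in range(i)
            ]
            pairs = np.stack([flat[:, idx[nm]] for nm in pair_names], axis=1)
            for s in range(S):
                R = _corr_matrix_from_pairs(pairs[s], Q)
                cov[s] = R * np.outer(sig[s], sig[s])
    return phi, cov


def _person_effect_batches(draws: PosteriorDraws, spec: ModelSpec, max_draws: int):
    """Per-(draw, person) phi and innovation covariance for random models."""
    if draws.person_draws is None:
        raise EstimationError("fit was run without stored person draws")
    C, S, N, K = draws.person_draws.shape
    E = draws.person_draws.reshape(C * S, N, K)
    flat = draws.flat()
    if max_draws and C * S > max_draws:
        sel = np.linspace(0, C * S - 1, max_draws).astype(int)
        E = E[sel]
        flat = flat[sel]
    S2 = E.shape[0]
    eff = draws.person_effect_names
    idx = {nm: i for i, nm in enumerate(draws.names)}
    Q = spec.n_constructs
    phi = np.empty((S2, N, len(spec.terms)))
    for j, t in enumerate(spec.terms):
        if t.random:
            phi[:, :, j] = E[:, :, eff.index(t.label)]
        else:
            phi[:, :, j] = flat[:, idx[t.label], None]
    if spec.random_innovation_variances:
        ln_d = np.stack(
            [E[:, :, eff.index(f"ln_sigma2_delta_{q + 1}")] for q in range(Q)], axis=2
        )
        if spec.innovation_covariance == "random":
            lnf = E[:, :, eff.index("ln_sigma2_etazeta")]
            cov = dynamics.common_factor_cov(
                ln_d.reshape(S2 * N, Q),
                lnf.reshape(S2 * N),
                spec.innovation_covariance_sign,
            ).reshape(S2, N, Q, Q)
        else:
            cov = np.zeros((S2, N, Q, Q))
            cov[:, :, np.arange(Q), np.arange(Q)] = np.exp(ln_d)
    else:
        sig = np.stack(
            [flat[:, idx[f"sigma_zeta_{q + 1}"]] for q in range(Q)], axis=1
        )
        cov = np.zeros((S2, N, Q, Q))
        cov[:, :, np.arange(Q), np.arange(Q)] = (sig**2)[:, None, :]
    return phi, cov


def _implied_moments(spec, phi, cov, n_steps, burn_in, seed):
    """State and regressor SDs for a batch of parameter sets.

    Uses the closed-form stationary covariance when the model has no
    interaction terms, otherwise a common-random-number forward
    simulation of ``n_steps`` retained steps.
    """
    has_interaction = any(t.kind == "interaction" for t in spec.terms)
    B = phi.shape[0]
    Q = spec.n_constructs
    if not has_interaction:
        S = dynamics.stationary_cov_linear(spec, phi, cov)
        state_var = S[:, np.arange(Q), np.arange(Q)]
        state_sd = np.sqrt(state_var)
        reg_sd = np.empty((B, len(spec.terms)))
        for j, t in enumerate(spec.terms):
            reg_sd[:, j] = state_sd[:, t.predictor]
        finite = np.isfinite(state_var).all(axis=1)
        return state_sd, state_var, reg_sd, finite
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    mom = dynamics.simulate_moments(spec, phi, chol, n_steps, burn_in, rng, bound=1e6)
    state_sd = mom["state_sd"]
    reg_sd = mom["regressor_sd"].copy()
    # lagged plain states share the stationary distribution of the state:
    # use the (less noisy) state SD for AR/CR regressors
    for j, t in enumerate(spec.terms):
        if t.kind != "interaction":
            reg_sd[:, j] = state_sd[:, t.predictor]
    return state_sd, mom["state_var"], reg_sd, mom["finite"]


def standardize(
    draws: PosteriorDraws,
    spec: ModelSpec,
    n_steps: int = 100_000,
    burn_in: int = 500,
    seed: int = 0,
    max_draws: int = 200,
) -> StandardizedDraws:
    """Within-person standardization of all dynamic coefficients.

    Per draw, ``std = phi * SD(regressor) / SD(outcome state)`` with
    model-implied within-person SDs.  Random-effects models standardize
    per person (``max_draws`` thins the posterior for the per-person
    simulations) and report the across-person average per draw.
    Non-stationary draws (non-finite implied moments) are excluded and
    counted.
    """
    if spec.has_random_phi or spec.random_innovation_variances:
        phi, cov = _person_effect_batches(draws, spec, max_draws)
        S2, N, J = phi.shape
        Q = spec.n_constructs
        state_sd, state_var, reg_sd, finite = _implied_moments(
            spec,
            phi.reshape(S2 * N, J),
            cov.reshape(S2 * N, Q, Q),
            n_steps,
            burn_in,
            seed,
        )
        state_sd = state_sd.reshape(S2, N, Q)
        reg_sd = reg_sd.reshape(S2, N, J)
        finite = finite.reshape(S2, N).all(axis=1)
        person_coefs = np.empty((S2, N, J))
        for j, t in enumerate(spec.terms):
            person_coefs[:, :, j] = phi[:, :, j] * reg_sd[:, :, j] / state_sd[:, :, t.outcome]
        coefs = person_coefs.mean(axis=1)
        n_excl = int((~finite).sum())
        inn_var = cov.reshape(S2, N, Q, Q)[:, :, np.arange(Q), np.arange(Q)].mean(axis=1)
        return StandardizedDraws(
            term_labels=[t.label for t in spec.terms],
            coefs=coefs[finite],
            unstandardized=phi.mean(axis=1)[finite],
            state_sd=state_sd.mean(axis=1)[finite],
            innovation_var=inn_var[finite],
            person_coefs=person_coefs[finite],
            n_excluded=n_excl,
        )
    phi, cov = _fixed_effect_batches(draws, spec)
    state_sd, state_var, reg_sd, finite = _implied_moments(
        spec, phi, cov, n_steps, burn_in, seed
    )
    J = len(spec.terms)
    coefs = np.empty_like(phi)
    for j, t in enumerate(spec.terms):
        coefs[:, j] = phi[:, j] * reg_sd[:, j] / state_sd[:, t.outcome]
    Q = spec.n_constructs
    inn_var = cov[:, np.arange(Q), np.arange(Q)]
    return StandardizedDraws(
        term_labels=[t.label for t in spec.terms],
        coefs=coefs[finite],
        unstandardized=phi[finite],
        state_sd=state_sd[finite],
        innovation_var=inn_var[finite],
        n_excluded=int((~finite).sum()),
    )


# ---------------------------------------------------------------------------
# Interaction surfaces
# ---------------------------------------------------------------------------

@dataclass
class InteractionSurface:
    """Predicted values/slopes over a moderator x predictor grid."""

    moderator_values: np.ndarray
    predictor_grid: np.ndarray
    mean: np.ndarray  # (n_moderator, n_predictor)
    lo: np.ndarray
    hi: np.ndarray
    slope_mean: np.ndarray  # per moderator value
    slope_lo: np.ndarray
    slope_hi: np.ndarray
    significant: np.ndarray  # slope CI excludes zero, per moderator value

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.moderator_values):
            for j, x in enumerate(self.predictor_grid):
                rows.append((m, x, self.mean[i, j], self.lo[i, j], self.hi[i, j]))
        return pd.DataFrame(rows, columns=["moderator", "predictor", "mean", "lo", "hi"])


def _infer_interaction(std: StandardizedDraws, spec: ModelSpec, interaction: str | None):
    labels = std.term_labels
    inter_terms = [t for t in spec.terms if t.kind == "interaction"]
    if not inter_terms:
        raise ConfigurationError("model has no interaction term")
    if interaction is None:
        term = inter_terms[0]
    else:
        term = next((t for t in inter_terms if t.label == interaction), None)
        if term is None:
            raise ConfigurationError(f"no interaction term {interaction!r}")
    # the focal predictor is the one that also has a CR path to the outcome;
    # the moderator is the other state entering the product
    cr_term = None
    for t in spec.terms:
        if t.kind == "CR" and t.outcome == term.outcome and t.predictor in (
            term.predictor,
            term.second_predictor,
        ):
            cr_term = t
            break
    if cr_term is None:
        raise ConfigurationError("no CR main effect matching the interaction")
    moderator = (
        term.second_predictor if cr_term.predictor == term.predictor else term.predictor
    )
    return term, cr_term, moderator


def simple_slopes(
    std: StandardizedDraws,
    spec: ModelSpec,
    moderator_values=(-1.0, 0.0, 1.0),
    predictor_range=(-2.5, 2.5),
    n_grid: int = 41,
    interaction: str | None = None,
    ar_outcome_level: float | None = None,
) -> InteractionSurface:
    """Predicted outcome across a predictor grid at selected moderator values.

    All quantities are on the standardized scale.  Per draw, the slope of
    the focal predictor is ``CR + interaction * moderator``; the predicted
    outcome adds ``AR * ar_outcome_level`` when a fixed previous outcome
    level is requested.  Surfaces summarize the draws by mean and 2.5/97.5
    percent quantiles.
    """
    term, cr_term, _ = _infer_interaction(std, spec, interaction)
    labels = std.term_labels
    j_int = labels.index(term.label)
    j_cr = labels.index(cr_term.label)
    mod = np.asarray(moderator_values, dtype=float)
    grid = np.linspace(predictor_range[0], predictor_range[1], n_grid)
    slopes = std.coefs[:, None, j_cr] + std.coefs[:, None, j_int] * mod[None, :]
    offset = 0.0
    if ar_outcome_level is not None:
        j_ar = next(
            labels.index(t.label)
            for t in spec.terms
            if t.kind == "AR" and t.outcome == term.outcome
        )
        offset = std.coefs[:, None, j_ar] * ar_outcome_level
    pred = slopes[:, :, None] * grid[None, None, :]
    if np.ndim(offset):
        pred = pred + offset[:, :, None]
    lo, hi = np.quantile(pred, [0.025, 0.975], axis=0)
    s_lo, s_hi = np.quantile(slopes, [0.025, 0.975], axis=0)
    return InteractionSurface(
        moderator_values=mod,
        predictor_grid=grid,
        mean=pred.mean(axis=0),
        lo=lo,
        hi=hi,
        slope_mean=slopes.mean(axis=0),
        slope_lo=s_lo,
        slope_hi=s_hi,
        significant=(s_lo > 0) | (s_hi < 0),
    )


def region_of_significance(
    std: StandardizedDraws,
    spec: ModelSpec,
    moderator_grid=None,
    interaction: str | None = None,
):
    """Moderator values where the 95% CI of the conditional slope excludes 0.

    Returns a dict with the grid, slope mean/CI, a significance mask and
    the interpolated boundary values where the CI starts/stops covering
    zero (quantile-based across draws, not an analytic boundary).
    """
    if moderator_grid is None:
        moderator_grid = np.linspace(-2.5, 2.5, 201)
    term, cr_term, _ = _infer_interaction(std, spec, interaction)
    labels = std.term_labels
    j_int = labels.index(term.label)
    j_cr = labels.index(cr_term.label)
    grid = np.asarray(moderator_grid, dtype=float)
    slopes = std.coefs[:, None, j_cr] + std.coefs[:, None, j_int] * grid[None, :]
    lo, hi = np.quantile(slopes, [0.025, 0.975], axis=0)
    mean = slopes.mean(axis=0)
    sig = (lo > 0) | (hi < 0)
    boundaries = []
    for i in range(1, len(grid)):
        if sig[i] != sig[i - 1]:
            # interpolate on whichever CI bound crosses zero
            for bound in (lo, hi):
                a, b = bound[i - 1], bound[i]
                if (a > 0) != (b > 0):
                    x = grid[i - 1] + (0.0 - a) / (b - a) * (grid[i] - grid[i - 1])
                    boundaries.append(float(x))
                    break
            else:
                boundaries.append(float(grid[i]))
    return {
        "moderator": grid,
        "slope_mean": mean,
        "slope_lo": lo,
        "slope_hi": hi,
        "significant": sig,
        "boundaries": boundaries,
    }


# ---------------------------------------------------------------------------
# Variance explained and reliabilities
# ---------------------------------------------------------------------------

def variance_explained(
    draws: PosteriorDraws,
    spec: ModelSpec,
    outcome: int,
    n_steps: int = 100_000,
    burn_in: int = 500,
    seed: int = 0,
):
    """Per-draw share of within-level true-score variance explained.

    ``R^2 = 1 - Var(innovation) / Var(state)`` with the model-implied
    stationary within-person variance of the outcome construct.  Returns
    (r2_draws, summary dict).
    """
    phi, cov = _fixed_effect_batches(draws, spec)
    state_sd, state_var, _, finite = _implied_moments(
        spec, phi, cov, n_steps, burn_in, seed
    )
    inn = cov[:, outcome, outcome]
    r2 = 1.0 - inn[finite] / state_var[finite, outcome]
    lo, hi = np.quantile(r2, [0.025, 0.975])
    return r2, {
        "mean": float(r2.mean()),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "n_excluded": int((~finite).sum()),
    }


def item_reliability(
    draws: PosteriorDraws,
    spec: ModelSpec,
    n_steps: int = 100_000,
    burn_in: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-implied within-level reliability per indicator.

    ``rel = lambda^2 Var(eta^w) / (lambda^2 Var(eta^w) + theta_w)`` per
    draw, summarized by posterior mean and 95% CI.
    """
    if not spec.any_factor:
        raise ConfigurationError("item reliabilities require a measurement model")
    phi, cov = _fixed_effect_batches(draws, spec)
    state_sd, state_var, _, finite = _implied_moments(
        spec, phi, cov, n_steps, burn_in, seed
    )
    flat = draws.flat()
    idx = {nm: i for i, nm in enumerate(draws.names)}
    rows = []
    for q, c in enumerate(spec.constructs):
        if c.single_indicator:
            continue
        for p in range(c.n_indicators):
            lam = (
                np.ones(flat.shape[0])
                if p == 0 or not c.loadings_free
                else flat[:, idx[f"lambda_w_{q + 1}_{p + 1}"]]
            )
            theta = flat[:, idx[f"sigma_eps_w_{q + 1}_{p + 1}"]] ** 2
            num = lam[finite] ** 2 * state_var[finite, q]
            rel = num / (num + theta[finite])
            lo, hi = np.quantile(rel, [0.025, 0.975])
            rows.append(
                (c.name, p + 1, float(rel.mean()), float(lo), float(hi))
            )
    return pd.DataFrame(
        rows, columns=["construct", "item", "reliability", "q2.5", "q97.5"]
    )


def plot_interaction(surface: InteractionSurface, ax=None, labels=None):
    """Line plot of the predicted-outcome surface (one line per moderator
    value, dashed 95% band).  The numeric surface is the tested artifact;
    this is a convenience view."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, mv in enumerate(surface.moderator_values):
        lbl = labels[i] if labels else f"moderator = {mv:+.1f} SD"
        (line,) = ax.plot(surface.predictor_grid, surface.mean[i], label=lbl)
        ax.plot(surface.predictor_grid, surface.lo[i], "--", lw=0.8, color=line.get_color())
        ax.plot(surface.predictor_grid, surface.hi[i], "--", lw=0.8, color=line.get_color())
    ax.set_xlabel("predictor (within-person SD)")
    ax.set_ylabel("predicted outcome (standardized)")
    ax.legend()
    return ax


def random_effect_summaries(
    draws: PosteriorDraws,
    spec: ModelSpec,
    std: StandardizedDraws | None = None,
    **std_kwargs,
):
    """Person-level estimates and cross-person spread for random effects.

    Returns a dict with ``person_table`` (per-person posterior means of
    the standardized dynamic effects), ``central95`` (the central 95%
    interval of person estimates per term), and ``correlations`` (posterior
    means of the between-level random-effect correlations).
    """
    if not (spec.has_random_phi or spec.random_innovation_variances):
        raise ConfigurationError("random-effect summaries require a random-effects model")
    if std is None:
        std = standardize(draws, spec, **std_kwargs)
    if std.person_coefs is None:
        raise ConfigurationError("standardized draws lack person-level values")
    person_means = std.person_coefs.mean(axis=0)  # (N, terms)
    table = pd.DataFrame(person_means, columns=std.term_labels)
    if draws.person_index is not None:
        table.insert(0, "person", draws.person_index)
    central95 = {
        lbl: tuple(np.quantile(person_means[:, j], [0.025, 0.975]))
        for j, lbl in enumerate(std.term_labels)
    }
    flat = draws.flat()
    corr = {
        nm: float(flat[:, i].mean())
        for i, nm in enumerate(draws.names)
        if nm.startswith("rho(") and "zeta_" not in nm
    }
    return {
        "person_table": table,
        "central95": central95,
        "correlations": pd.Series(corr),
    }
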