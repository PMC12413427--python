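"""Within-person dynamic recursion shared by simulator, estimator and
post-processing.

The within-level model is a VAR(1) in the latent person-mean-centered
states, augmented with pairwise product (interaction) terms and,
optionally, same-occasion (lag-0) predictors.  All functions here are
vectorized over a batch axis (persons, posterior draws, or person x draw
combinations) with a plain time loop, which keeps a single code path for
data generation, stationarity screening and model-implied moments.
"""

from __future__ import annotations

import numpy as np

from .errors import SimulationError
from .modelspec import ModelSpec

__all__ = [
    "term_arrays",
    "linearized_matrices",
    "companion_spectral_radius",
    "stationary_cov_linear",
    "common_factor_cov",
    "simulate_series",
    "simulate_moments",
]


def term_arrays(spec: ModelSpec, phi: np.ndarray):
    """Bundle term metadata with coefficient columns.

    ``phi`` has shape (B, n_terms) -- one coefficient per term per batch
    element.  Returns a list of (outcome, predictor, lag, second_predictor,
    second_lag, coef_column) tuples in spec term order.
    """
    phi = np.atleast_2d(phi)
    out = []
    for j, t in enumerate(spec.terms):
        out.append((t.outcome, t.predictor, t.lag, t.second_predictor, t.second_lag, phi[:, j]))
    return out


def linearized_matrices(spec: ModelSpec, phi: np.ndarray):
    """Lag-1 and lag-0 coefficient matrices of the linearized system.

    Interaction terms are evaluated at moderator = 0 and therefore drop
    out of the linearization.  Shapes: (B, Q, Q) each.
    """
    phi = np.atleast_2d(phi)
    B, Q = phi.shape[0], spec.n_constructs
    A1 = np.zeros((B, Q, Q))
    A0 = np.zeros((B, Q, Q))
    for j, t in enumerate(spec.terms):
        if t.kind == "interaction":
            continue
        target = A1 if t.lag == 1 else A0
        target[:, t.outcome, t.predictor] += phi[:, j]
    return A1, A0


def reduced_form(spec: ModelSpec, phi: np.ndarray):
    """Reduced-form transition matrix (I - A0)^-1 A1 and mixing (I - A0)^-1."""
    A1, A0 = linearized_matrices(spec, phi)
    Q = spec.n_constructs
    eye = np.eye(Q)
    Binv = np.linalg.inv(eye[None] - A0)
    return Binv @ A1, Binv


def companion_spectral_radius(spec: ModelSpec, phi: np.ndarray) -> np.ndarray:
    """Spectral radius of the linearized reduced-form transition matrix."""
    Phi, _ = reduced_form(spec, phi)
    eig = np.linalg.eigvals(Phi)
    return np.abs(eig).max(axis=-1)


def stationary_cov_linear(spec: ModelSpec, phi: np.ndarray, innov_cov: np.ndarray) -> np.ndarray:
    """Closed-form stationary state covariance of the linearized VAR(1).

    Solves vec(Sigma) = (I - Phi (x) Phi)^-1 vec(B Sigma_zeta B') per batch
    element, where Phi is the reduced-form transition matrix and B the
    lag-0 mixing matrix.  Non-stationary elements yield NaN entries.
    """
    phi = np.atleast_2d(phi)
    innov_cov = np.asarray(innov_cov)
    if innov_cov.ndim == 2:
        innov_cov = np.broadcast_to(innov_cov, (phi.shape[0],) + innov_cov.shape)
    Phi, Binv = reduced_form(spec, phi)
    S = Binv @ innov_cov @ np.swapaxes(Binv, -1, -2)
    B, Q = phi.shape[0], spec.n_constructs
    eye = np.eye(Q * Q)
    kron = np.einsum("bij,bkl->bikjl", Phi, Phi).reshape(B, Q * Q, Q * Q)
    out = np.full((B, Q, Q), np.nan)
    rad = np.abs(np.linalg.eigvals(Phi)).max(axis=-1)
    ok = rad < 1.0
    if ok.any():
        rhs = S[ok].reshape(-1, Q * Q, 1)
        sol = np.linalg.solve(eye[None] - kron[ok], rhs)
        out[ok] = sol.reshape(-1, Q, Q)
    return out


def common_factor_cov(
    ln_sigma2_delta: np.ndarray,
    ln_sigma2_etazeta: np.ndarray,
    sign: int = 1,
) -> np.ndarray:
    """Innovation covariance implied by the common-factor construction.

    Each innovation is the sum of a shared factor and a construct-specific
    residual, ``zeta_q = c_q * eta_zeta + delta_q`` with ``c_1 = 1`` and
    ``c_q = sign`` for q > 1, so Var(zeta_q) = sigma2_etazeta + sigma2_delta_q
    and Cov(zeta_q, zeta_q') = c_q c_q' sigma2_etazeta.  All variance
    components are exp() of the supplied log-variances, hence the implied
    matrix is positive definite for any finite input.
    """
    ln_sigma2_delta = np.atleast_2d(ln_sigma2_delta)
    B, Q = ln_sigma2_delta.shape
    s2d = np.exp(ln_sigma2_delta)
    s2f = np.exp(np.atleast_1d(ln_sigma2_etazeta)).reshape(B)
    c = np.ones(Q)
    c[1:] = sign
    cov = s2f[:, None, None] * np.outer(c, c)[None]
    cov[:, np.arange(Q), np.arange(Q)] += s2d
    return cov


def _step(spec_terms, eta_prev, zeta, lag0_order, Q):
    """One recursion step; returns eta_t given eta_{t-1} and innovations."""
    B = zeta.shape[0]
    eta_t = zeta.copy()
    for q in lag0_order:
        acc = eta_t[:, q]
        for (outcome, pred, lag, pred2, lag2, coef) in spec_terms:
            if outcome != q:
                continue
            x = eta_prev[:, pred] if lag == 1 else eta_t[:, pred]
            if pred2 is not None:
                x = x * (eta_prev[:, pred2] if lag2 == 1 else eta_t[:, pred2])
            acc = acc + coef * x
        eta_t[:, q] = acc
    return eta_t


def simulate_series(
    spec: ModelSpec,
    phi: np.ndarray,
    innov_chol: np.ndarray,
    T: int,
    burn_in: int,
    rng: np.random.Generator,
    check_finite: bool = True,
) -> np.ndarray:
    """Simulate latent state series of length T after ``burn_in`` steps.

    ``phi`` has shape (B, n_terms), ``innov_chol`` (B, Q, Q) lower
    Cholesky factors of the innovation covariances.  Initial state is
    zero.  Returns (B, T, Q).
    """
    phi = np.atleast_2d(phi)
    B, Q = phi.shape[0], spec.n_constructs
    terms = term_arrays(spec, phi)
    order = spec.lag0_order()
    eta = np.zeros((B, Q))
    out = np.empty((B, T, Q))
    total = burn_in + T
    noise = rng.standard_normal((total, B, Q))
    for t in range(total):
        zeta = np.einsum("bqr,br->bq", innov_chol, noise[t])
        eta = _step(terms, eta, zeta, order, Q)
        if t >= burn_in:
            out[:, t - burn_in] = eta
    if check_finite and not np.isfinite(out).all():
        bad = np.flatnonzero(~np.isfinite(out).all(axis=(1, 2)))
        raise SimulationError(
            f"non-finite latent trajectory for batch element(s) {bad.tolist()}"
        )
    return out


def simulate_moments(
    spec: ModelSpec,
    phi: np.ndarray,
    innov_chol: np.ndarray,
    n_steps: int,
    burn_in: int,
    rng: np.random.Generator,
    bound: float | None = None,
):
    """Long-run empirical moments of states and term regressors.

    Runs the recursion for ``burn_in + n_steps`` steps and accumulates
    running first/second moments of (a) each latent state and (b) each
    dynamic term's regressor (the lagged state, or the product of the two
    lagged states for interaction terms).  Returns a dict with ``state_sd``
    (B, Q), ``state_var``, ``regressor_sd`` (B, n_terms) and ``finite``
    (B,) flags; trajectories exceeding ``bound`` (or turning non-finite)
    are flagged and reported as NaN.
    """
    phi = np.atleast_2d(phi)
    B, Q = phi.shape[0], spec.n_constructs
    terms = term_arrays(spec, phi)
    order = spec.lag0_order()
    eta = np.zeros((B, Q))
    s1 = np.zeros((B, Q))
    s2 = np.zeros((B, Q))
    r1 = np.zeros((B, len(terms)))
    r2 = np.zeros((B, len(terms)))
    alive = np.ones(B, dtype=bool)
    noise = None
    chunk = 2048
    count = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(burn_in + n_steps):
            k = t % chunk
            if k == 0:
                noise = rng.standard_normal((min(chunk, burn_in + n_steps - t), B, Q))
            zeta = np.einsum("bqr,br->bq", innov_chol, noise[k])
            eta_prev = eta
            eta = _step(terms, eta_prev, zeta, order, Q)
            if bound is not None and t % 64 == 0:
                with np.errstate(invalid="ignore"):
                    alive &= np.isfinite(eta).all(axis=1) & (np.abs(eta) < bound).all(axis=1)
                eta[~alive] = 0.0  # keep the arithmetic finite for dead elements
            if t >= burn_in:
                count += 1
                s1 += eta
                s2 += eta * eta
                for j, (outcome, pred, lag, pred2, lag2, coef) in enumerate(terms):
                    x = eta_prev[:, pred] if lag == 1 else eta[:, pred]
                    if pred2 is not None:
                        x = x * (eta_prev[:, pred2] if lag2 == 1 else eta[:, pred2])
                    r1[:, j] += x
                    r2[:, j] += x * x
        alive &= np.isfinite(eta).all(axis=1)
        state_var = s2 / count - (s1 / count) ** 2
        reg_var = r2 / count - (r1 / count) ** 2
    state_var[~alive] = np.nan
    reg_var[~alive] = np.nan
    return {
        "state_var": state_var,
        "state_sd": np.sqrt(np.maximum(state_var, 0.0)),
        "regressor_sd": np.sqrt(np.maximum(reg_var, 0.0)),
        "finite": alive,
    }
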