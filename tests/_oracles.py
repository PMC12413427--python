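"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain per-term loops over
persons, occasions and model terms, using scipy densities, so that it
shares no code path with the package's vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg as sla
from scipy import stats


def half_cauchy_logpdf(x, scale):
    if x <= 0:
        return -math.inf
    return math.log(2.0) - math.log(math.pi * scale * (1.0 + (x / scale) ** 2))


def _term_value(term, eta_prev, eta_now):
    src = eta_prev if term.lag == 1 else eta_now
    x = src[term.predictor]
    if term.second_predictor is not None:
        src2 = eta_prev if term.second_lag == 1 else eta_now
        x = x * src2[term.second_predictor]
    return x


def linearized_stationary_cov(spec, phi_vals, innov_cov):
    """Stationary covariance of the linearized system via scipy's
    discrete Lyapunov solver (independent of the package's vec-solve)."""
    Q = spec.n_constructs
    A1 = np.zeros((Q, Q))
    A0 = np.zeros((Q, Q))
    for j, t in enumerate(spec.terms):
        if t.kind == "interaction":
            continue
        (A1 if t.lag == 1 else A0)[t.outcome, t.predictor] += phi_vals[j]
    Binv = np.linalg.inv(np.eye(Q) - A0)
    Phi = Binv @ A1
    if np.abs(np.linalg.eigvals(Phi)).max() >= 1.0:
        return None
    return sla.solve_discrete_lyapunov(Phi, Binv @ innov_cov @ Binv.T)


def naive_log_density(
    spec,
    priors,
    panel,
    globals_constrained: dict,
    Z: np.ndarray,
    latent: dict | None = None,
    miss: dict | None = None,
    initial_state: str = "stationary",
) -> float:
    """Term-by-term joint log posterior; mirrors the model semantics with
    plain loops.  Correlation parameters must be zero (identity matrices)
    so that no shared correlation-transform code is exercised."""
    from mlmvar.modelspec import parameter_index, person_effect_names

    latent = latent or {}
    miss = miss or {}
    arr = panel.to_arrays(spec)
    y, present, lag_valid = arr["y"], arr["present"], arr["lag_valid"] & arr["present"]
    N, T, P = y.shape
    Q = spec.n_constructs
    pidx = parameter_index(spec)
    eff = person_effect_names(spec)
    K = len(eff)
    gc = globals_constrained

    total = 0.0
    # ---- global priors (incl. log-scale Jacobians) -------------------
    for e in pidx.entries:
        nm = e.name
        if e.group is not None:
            continue  # correlations fixed at zero contribute 0 under LKJ(1)
        v = gc[nm]
        if e.category == "phi":
            total += stats.norm.logpdf(v, 0.0, priors.phi_scale)
        elif nm.startswith("sigma_zeta_"):
            total += half_cauchy_logpdf(v, priors.innovation_scale_cauchy) + math.log(v)
        elif nm.startswith("gamma_ln_sigma2"):
            total += stats.norm.logpdf(v, 0.0, priors.log_innovation_scale)
        elif nm.startswith("gamma_mu_"):
            total += stats.norm.logpdf(v, 0.0, priors.trait_mean_scale)
        elif e.category == "re_scale":
            stem = nm[4:]
            scale = (
                priors.phi_scale_cauchy
                if stem.startswith("phi_")
                else priors.trait_scale_cauchy
                if stem.startswith("mu_")
                else priors.log_innovation_scale_cauchy
            )
            total += half_cauchy_logpdf(v, scale) + math.log(v)
        elif nm.startswith("lambda_"):
            total += stats.norm.logpdf(v, priors.loading_mean, priors.loading_scale)
        elif nm.startswith("alpha_"):
            total += stats.norm.logpdf(v, 0.0, priors.intercept_scale)
        elif nm.startswith("sigma_eps_"):
            total += half_cauchy_logpdf(v, priors.measurement_error_cauchy) + math.log(v)

    # ---- person effects (non-centered, identity correlation) ---------
    gamma = np.empty(K)
    tau = np.empty(K)
    for k, nm in enumerate(eff):
        gamma[k] = gc["gamma_" + nm] if not nm.startswith("phi") else gc[nm]
        tau[k] = gc["tau_" + nm]
    E = np.empty((N, K))
    for i in range(N):
        for k in range(K):
            total += stats.norm.logpdf(Z[i, k], 0.0, 1.0)
            E[i, k] = gamma[k] + tau[k] * Z[i, k]

    # ---- per-person parameter assembly -------------------------------
    col0 = {}
    start = 0
    for q, c in enumerate(spec.constructs):
        col0[q] = start
        start += c.n_indicators

    def person_phi(i):
        out = np.empty(len(spec.terms))
        for j, t in enumerate(spec.terms):
            out[j] = E[i, eff.index(t.label)] if t.random else gc[t.label]
        return out

    def person_cov(i):
        if spec.random_innovation_variances:
            s2d = np.array(
                [math.exp(E[i, eff.index(f"ln_sigma2_delta_{q + 1}")]) for q in range(Q)]
            )
            cov = np.diag(s2d)
            if spec.innovation_covariance == "random":
                s2f = math.exp(E[i, eff.index("ln_sigma2_etazeta")])
                c = np.ones(Q)
                c[1:] = spec.innovation_covariance_sign
                cov = cov + s2f * np.outer(c, c)
            return cov
        sig = np.array([gc[f"sigma_zeta_{q + 1}"] for q in range(Q)])
        return np.diag(sig**2)  # identity innovation correlation in oracle cases

    def person_eta(i):
        et = np.zeros((T, Q))
        for q, c in enumerate(spec.constructs):
            if c.single_indicator:
                for t in range(T):
                    if not present[i, t]:
                        continue
                    v = y[i, t, col0[q]]
                    et[t, q] = (v - E[i, q]) if np.isfinite(v) else np.nan
            else:
                et[:, q] = np.asarray(latent[q])[i]
        return et

    # free states at missing single-indicator cells
    miss_lookup = {}
    for q, c in enumerate(spec.constructs):
        if not c.single_indicator:
            continue
        cells = [
            (i, t)
            for i in range(N)
            for t in range(T)
            if present[i, t] and not np.isfinite(y[i, t, col0[q]])
        ]
        if cells:
            vals = np.asarray(miss[q])
            miss_lookup[q] = {cell: vals[m] for m, cell in enumerate(cells)}

    ll = 0.0
    for i in range(N):
        phi_i = person_phi(i)
        cov_i = person_cov(i)
        eta_i = person_eta(i)
        for q in miss_lookup:
            for (pi, t), v in miss_lookup[q].items():
                if pi == i:
                    eta_i[t, q] = v
        # measurement model
        for q, c in enumerate(spec.constructs):
            if c.single_indicator:
                continue
            Pq = c.n_indicators
            for p in range(Pq):
                lam_w = 1.0 if (p == 0 or not c.loadings_free) else gc[f"lambda_w_{q + 1}_{p + 1}"]
                lam_b = 1.0 if (p == 0 or not c.loadings_free) else gc[f"lambda_b_{q + 1}_{p + 1}"]
                alpha = 0.0 if p == 0 else gc[f"alpha_{q + 1}_{p + 1}"]
                sd = gc[f"sigma_eps_w_{q + 1}_{p + 1}"]
                for t in range(T):
                    v = y[i, t, col0[q] + p]
                    if present[i, t] and np.isfinite(v):
                        mean = alpha + lam_b * E[i, q] + lam_w * eta_i[t, q]
                        ll += stats.norm.logpdf(v, mean, sd)
                # anchor prior on latent states at absent grid cells
                if p == 0:
                    for t in range(T):
                        if not present[i, t]:
                            ll += stats.norm.logpdf(eta_i[t, q], 0.0, 1.0)
        # dynamics + initial states
        Sinf = linearized_stationary_cov(spec, phi_i, cov_i)
        for t in range(T):
            if not present[i, t]:
                continue
            if lag_valid[i, t]:
                resid = eta_i[t].copy()
                for j, term in enumerate(spec.terms):
                    resid[term.outcome] -= phi_i[j] * _term_value(
                        term, eta_i[t - 1], eta_i[t]
                    )
                ll += stats.multivariate_normal.logpdf(resid, np.zeros(Q), cov_i)
            elif initial_state == "stationary":
                if Sinf is None:
                    return -math.inf
                ll += stats.multivariate_normal.logpdf(eta_i[t], np.zeros(Q), Sinf)
    return float(total + ll)


# ---------------------------------------------------------------------------
# Rank-normalized split-Rhat (Vehtari et al. reference formulas)
# ---------------------------------------------------------------------------

def _split_chains(x):
    C, S = x.shape
    half = S // 2
    return np.vstack([x[:, :half], x[:, half : 2 * half]])


def _classic_rhat(chains):
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return math.sqrt(var_hat / W)


def _rank_normalize(x):
    from scipy.stats import rankdata, norm

    shape = x.shape
    r = rankdata(x.reshape(-1), method="average")
    z = norm.ppf((r - 3.0 / 8.0) / (x.size - 2.0 * 3.0 / 8.0 + 1.0))
    return z.reshape(shape)


def reference_split_rhat(x: np.ndarray) -> float:
    """Rank-normalized split-Rhat, max of bulk and folded variants."""
    s = _split_chains(x)
    bulk = _classic_rhat(_rank_normalize(s))
    folded = _classic_rhat(_rank_normalize(np.abs(s - np.median(s))))
    return max(bulk, folded)
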