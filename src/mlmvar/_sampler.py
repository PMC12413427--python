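"""Blocked adaptive Metropolis-within-Gibbs sampler.

Moves per iteration:

* adaptive random-walk Metropolis on global sub-blocks (dynamic +
  innovation parameters; between-level hyperparameters; measurement
  parameters), with proposal covariance learned during warm-up;
* ancillarity-sufficiency interweaving moves for every person-effect
  location (gamma) and scale (tau): the hyperparameter is moved while the
  person vectors are adjusted to keep the realized effects fixed, which
  decouples hyperparameters from the strongly data-informed person
  effects;
* a parallel per-person update of the (conditionally independent)
  standard-normal person vectors;
* a sequential-in-time sweep over free latent states (multiple-indicator
  constructs and missing single-indicator occasions) with per-cell
  accept/reject based on the local terms they enter.

All proposal scales adapt during warm-up only (Robbins-Monro towards
fixed acceptance targets) and stay frozen afterwards, so the post-warm-up
chain is a valid time-homogeneous Markov chain.
"""

from __future__ import annotations

import numpy as np

from ._transforms import chol_corr, lkj_chol_log_prior
from .errors import EstimationError


def _lr(it: int) -> float:
    """Robbins-Monro learning rate: aggressive early, smooth late."""
    return min(0.2, 2.0 * (it + 10.0) ** -0.7)


class _AdaptBlock:
    """Haario-style adaptive multivariate RWM proposal for one index set."""

    def __init__(self, idx: np.ndarray, target: float = 0.25):
        self.idx = np.asarray(idx, dtype=int)
        self.d = len(self.idx)
        self.target = 0.44 if self.d == 1 else target
        self.log_scale = np.log(0.3 / max(np.sqrt(self.d), 1.0))
        self.mean = np.zeros(self.d)
        self.m2 = np.zeros((self.d, self.d))
        self.count = 0
        self.chol = np.eye(self.d)

    def observe(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, x - self.mean)
        if self.count >= 50 and self.count % 50 == 0:
            cov = self.m2 / (self.count - 1) + 1e-9 * np.eye(self.d)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def propose(self, rng) -> np.ndarray:
        step = self.chol @ rng.standard_normal(self.d)
        return np.exp(self.log_scale) * step

    def adapt(self, accepted: float, it: int) -> None:
        lr = _lr(it)
        self.log_scale += lr * (accepted - self.target)


def _global_blocks(lp):
    cats = {"dyn": [], "lvl2": [], "meas": []}
    for i, e in enumerate(lp.pidx.entries):
        if e.category in ("phi", "innovation") or e.group == "inncorr":
            cats["dyn"].append(i)
        elif e.category == "measurement":
            cats["meas"].append(i)
        else:
            cats["lvl2"].append(i)
    # the data-dominated dynamic block gets two updates per iteration
    order = ["dyn", "dyn", "dyn", "lvl2", "lvl2", "meas"]
    return [np.array(cats[k], dtype=int) for k in order if cats[k]]


def run_chain(lp, iterations: int, warmup: int, rng: np.random.Generator) -> np.ndarray:
    """One MCMC chain; returns post-warm-up theta draws (keep, dim)."""
    theta = None
    for attempt in range(6):
        cand = lp.initial_theta(rng, jitter=1.0 / (attempt + 1))
        g, p = lp.evaluate(cand)
        if np.isfinite(g) and np.isfinite(p).all():
            theta = cand
            break
    if theta is None:
        raise EstimationError("could not find a finite starting point")

    blocks = [_AdaptBlock(idx) for idx in _global_blocks(lp)]
    loc_scales = np.full(lp.K, -1.5)  # log proposal SDs for interweaving moves
    scl_scales = np.full(lp.K, -1.5)
    corr_scale = np.log(0.3)
    person_scales = np.full(lp.N, np.log(0.5))
    latent_scale = np.log(0.5)

    keep = iterations - warmup
    out = np.empty((keep, lp.dim))
    total_p = p.sum()

    for it in range(iterations):
        adapting = it < warmup

        # ---- global blocks ------------------------------------------
        for b in blocks:
            prop = theta.copy()
            prop[b.idx] += b.propose(rng)
            g2, p2 = lp.evaluate(prop)
            t2 = p2.sum()
            logr = (g2 + t2) - (g + total_p)
            acc = np.log(rng.random()) < logr
            if acc:
                theta, g, p, total_p = prop, g2, p2, t2
            if adapting:
                b.adapt(float(acc), it)
                b.observe(theta[b.idx])

        # ---- interweaving moves on person-effect hyperparameters ----
        Z = theta[lp.z_off : lp.z_off + lp.n_z].reshape(lp.N, lp.K)
        L = chol_corr(theta[lp.recorr_idx], lp.K) if lp.K > 1 else np.eye(1)
        Linv = np.linalg.inv(L)
        for k in range(lp.K):
            # location: gamma_k += delta, effects held fixed
            gi = lp.gamma_eff_idx[k]
            tau_k = np.exp(theta[lp.tau_eff_idx[k]])
            delta = np.exp(loc_scales[k]) * rng.standard_normal()
            shift = Linv[:, k] * (delta / max(tau_k, 1e-12))
            Z2 = Z - shift[None, :]
            dzp = -0.5 * ((Z2 * Z2).sum(axis=1) - (Z * Z).sum(axis=1))
            dgp = lp.global_prior_entry(gi, theta[gi] + delta) - lp.global_prior_entry(
                gi, theta[gi]
            )
            acc = np.log(rng.random()) < dgp + dzp.sum()
            if acc:
                theta = theta.copy()
                theta[gi] += delta
                theta[lp.z_off : lp.z_off + lp.n_z] = Z2.reshape(-1)
                Z = Z2
                g += dgp
                p = p + dzp
                total_p = p.sum()
            if adapting:
                loc_scales[k] += _lr(it) * (float(acc) - 0.44)

            # scale: tau_k *= exp(eps), effects held fixed
            ti = lp.tau_eff_idx[k]
            eps = np.exp(scl_scales[k]) * rng.standard_normal()
            c = np.exp(eps)
            W = Z @ L.T
            W2 = W.copy()
            W2[:, k] /= c
            Z2 = W2 @ Linv.T
            dzp = -0.5 * ((Z2 * Z2).sum(axis=1) - (Z * Z).sum(axis=1))
            dgp = lp.global_prior_entry(ti, theta[ti] + eps) - lp.global_prior_entry(
                ti, theta[ti]
            )
            logr = dgp + dzp.sum() - lp.N * eps
            acc = np.log(rng.random()) < logr
            if acc:
                theta = theta.copy()
                theta[ti] += eps
                theta[lp.z_off : lp.z_off + lp.n_z] = Z2.reshape(-1)
                Z = Z2
                g += dgp
                p = p + dzp
                total_p = p.sum()
            if adapting:
                scl_scales[k] += _lr(it) * (float(acc) - 0.44)

        # ---- correlation interweave: move R, keep effects fixed -----
        if lp.K > 1 and len(lp.recorr_idx):
            zc = theta[lp.recorr_idx]
            step = np.exp(corr_scale) * rng.standard_normal(len(zc))
            zc2 = zc + step
            L2 = chol_corr(zc2, lp.K)
            Z2 = (Z @ L.T) @ np.linalg.inv(L2).T
            dzp = -0.5 * ((Z2 * Z2).sum(axis=1) - (Z * Z).sum(axis=1))
            dlkj = lkj_chol_log_prior(zc2, lp.K, lp.priors.lkj_eta) - lkj_chol_log_prior(
                zc, lp.K, lp.priors.lkj_eta
            )
            jac = lp.N * (
                np.log(np.diag(L)).sum() - np.log(np.diag(L2)).sum()
            )
            acc = np.log(rng.random()) < dlkj + dzp.sum() + jac
            if acc:
                theta = theta.copy()
                theta[lp.recorr_idx] = zc2
                theta[lp.z_off : lp.z_off + lp.n_z] = Z2.reshape(-1)
                Z, L = Z2, L2
                g += dlkj
                p = p + dzp
                total_p = p.sum()
            if adapting:
                corr_scale += _lr(it) * (float(acc) - 0.3)

        # ---- parallel per-person z update ---------------------------
        prop = theta.copy()
        step = np.exp(person_scales)[:, None] * rng.standard_normal((lp.N, lp.K))
        prop[lp.z_off : lp.z_off + lp.n_z] = (Z + step).reshape(-1)
        if lp.n_u:
            nu = lp.n_u // lp.N
            U = prop[lp.u_off : lp.u_off + lp.n_u].reshape(lp.N, nu)
            U += np.exp(person_scales)[:, None] * rng.standard_normal((lp.N, nu))
            prop[lp.u_off : lp.u_off + lp.n_u] = U.reshape(-1)
        g2, p2 = lp.evaluate(prop)
        acc_i = np.log(rng.random(lp.N)) < (p2 - p)
        if acc_i.any():
            Znew = np.where(acc_i[:, None], Z + step, Z)
            theta = theta.copy()
            theta[lp.z_off : lp.z_off + lp.n_z] = Znew.reshape(-1)
            if lp.n_u:
                nu = lp.n_u // lp.N
                Uold = theta[lp.u_off : lp.u_off + lp.n_u].reshape(lp.N, nu)
                Unew = prop[lp.u_off : lp.u_off + lp.n_u].reshape(lp.N, nu)
                theta[lp.u_off : lp.u_off + lp.n_u] = np.where(
                    acc_i[:, None], Unew, Uold
                ).reshape(-1)
            p = np.where(acc_i, p2, p)
            total_p = p.sum()
        if adapting:
            person_scales += _lr(it) * (acc_i.astype(float) - 0.3)

        # ---- latent-state sweep -------------------------------------
        if lp.has_latent:
            theta, p, acc_rate = _latent_sweep(lp, theta, p, np.exp(latent_scale), rng)
            total_p = p.sum()
            if adapting:
                latent_scale += _lr(it) * (acc_rate - 0.44)

        # ---- periodic cache resync ----------------------------------
        if (it + 1) % 256 == 0:
            g, p = lp.evaluate(theta)
            total_p = p.sum()

        if it >= warmup:
            out[it - warmup] = theta

    return out


def _resid_at(lp, phi_per, eta_prev, eta_t):
    """Dynamic residual vector (N, Q) at one occasion."""
    pred = np.zeros_like(eta_t)
    for j, t in enumerate(lp.spec.terms):
        src = eta_prev if t.lag == 1 else eta_t
        x = src[:, t.predictor]
        if t.second_predictor is not None:
            src2 = eta_prev if t.second_lag == 1 else eta_t
            x = x * src2[:, t.second_predictor]
        pred[:, t.outcome] += phi_per[:, j] * x
    return eta_t - pred


def _latent_sweep(lp, theta, p, scale, rng):
    """Sequential Metropolis sweep over free latent states.

    Updates, per occasion t, the latent-state components that are free
    parameters (all cells of multiple-indicator constructs; missing cells
    of single-indicator constructs), accepting per person based on the
    local measurement/dynamic/initial-state terms the cell enters.
    """
    gl = lp._globals(theta)
    Z, E = lp.person_effects(theta, gl)
    cov, inv, logdet = lp._innovation(theta, gl, E)
    if inv.ndim == 2:
        inv = np.broadcast_to(inv, (lp.N, lp.Q, lp.Q))
    phi_per = lp.phi_per_person(gl, E)
    eta = lp._latent_eta(theta, gl, E)

    init_inv = None
    if lp.initial_state == "stationary":
        S = lp._stationary_covs(phi_per, cov)
        ok = np.isfinite(S).all(axis=(1, 2))
        init_inv = np.zeros_like(S)
        if ok.any():
            init_inv[ok] = np.linalg.inv(S[ok])

    miss_mask = {}
    for q, cells in lp.miss_cells.items():
        m = np.zeros((lp.N, lp.T), dtype=bool)
        m[cells[:, 0], cells[:, 1]] = True
        miss_mask[q] = m

    n_acc = 0
    n_tot = 0
    for t in range(lp.T):
        free = np.zeros((lp.N, lp.Q), dtype=bool)
        for q in lp.factor_qs:
            free[:, q] = True
        for q, m in miss_mask.items():
            free[:, q] = m[:, t]
        if not free.any():
            continue
        rows = free.any(axis=1)
        eta_t = eta[:, t]
        eta_new = eta_t + np.where(free, scale * rng.standard_normal((lp.N, lp.Q)), 0.0)

        delta = np.zeros(lp.N)
        lv_t = lp.lag_valid[:, t]
        if lv_t.any():
            r_old = _resid_at(lp, phi_per, eta[:, t - 1], eta_t)
            r_new = _resid_at(lp, phi_per, eta[:, t - 1], eta_new)
            q_old = np.einsum("nq,nqr,nr->n", r_old, inv, r_old)
            q_new = np.einsum("nq,nqr,nr->n", r_new, inv, r_new)
            delta += np.where(lv_t, -0.5 * (q_new - q_old), 0.0)
        st_t = lp.start_mask[:, t]
        if init_inv is not None and st_t.any():
            q_old = np.einsum("nq,nqr,nr->n", eta_t, init_inv, eta_t)
            q_new = np.einsum("nq,nqr,nr->n", eta_new, init_inv, eta_new)
            delta += np.where(st_t, -0.5 * (q_new - q_old), 0.0)
        if t + 1 < lp.T:
            lv_n = lp.lag_valid[:, t + 1]
            if lv_n.any():
                r_old = _resid_at(lp, phi_per, eta_t, eta[:, t + 1])
                r_new = _resid_at(lp, phi_per, eta_new, eta[:, t + 1])
                q_old = np.einsum("nq,nqr,nr->n", r_old, inv, r_old)
                q_new = np.einsum("nq,nqr,nr->n", r_new, inv, r_new)
                delta += np.where(lv_n, -0.5 * (q_new - q_old), 0.0)
        for q in lp.factor_qs:
            m = gl["meas"][q]
            cols = lp.col_slices[q]
            obs = lp.obs_mask[q][:, t]  # (N, Pq)
            mu_items = m["alpha"][None, :] + m["lambda_b"][None, :] * E[:, q, None]
            if lp.spec.between_errors:
                Pq = cols.stop - cols.start
                qpos = lp.factor_qs.index(q)
                base = lp.u_off + lp.N * sum(
                    lp.spec.constructs[fq].n_indicators for fq in lp.factor_qs[:qpos]
                )
                zu = theta[base : base + lp.N * Pq].reshape(lp.N, Pq)
                mu_items = mu_items + zu * m["sigma_eps_b"][None, :]
            yqt = lp.y[:, t, cols]
            sd = m["sigma_eps_w"][None, :]
            r_old = (yqt - mu_items - m["lambda_w"][None, :] * eta_t[:, q, None]) / sd
            r_new = (yqt - mu_items - m["lambda_w"][None, :] * eta_new[:, q, None]) / sd
            dq = np.where(obs, -0.5 * (r_new**2 - r_old**2), 0.0).sum(axis=1)
            delta += dq
            absent = ~lp.present[:, t]
            if absent.any():
                delta += np.where(
                    absent, -0.5 * (eta_new[:, q] ** 2 - eta_t[:, q] ** 2), 0.0
                )

        acc = (np.log(rng.random(lp.N)) < delta) & rows & np.isfinite(delta)
        eta[:, t] = np.where(acc[:, None] & free, eta_new, eta_t)
        p = p + np.where(acc, delta, 0.0)
        n_acc += int(acc.sum())
        n_tot += int(rows.sum())

    theta = theta.copy()
    for q in lp.factor_qs:
        o = lp.latent_off[q]
        theta[o : o + lp.N * lp.T] = eta[:, :, q].reshape(-1)
    for q, cells in lp.miss_cells.items():
        o = lp.miss_off[q]
        theta[o : o + len(cells)] = eta[cells[:, 0], cells[:, 1], q]
    return theta, p, (n_acc / max(n_tot, 1))
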