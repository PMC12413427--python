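"""Bayesian posterior for multilevel latent moderated VAR models.

The joint log posterior combines (a) the measurement likelihood of the
observed indicators given latent person means and within-person states,
(b) the within-level moderated VAR likelihood of the latent states given
their lagged values (skipped wherever ``lag_valid`` is False, i.e. at day
and wave starts), (c) the between-level multivariate normal of all
person-varying effects, and (d) weakly informative priors.

Person-varying effects are parameterized non-centered: the sampler works
on standard-normal person vectors ``z_i`` with effects
``gamma + diag(tau) L z_i`` where ``L`` is the Cholesky factor of the
between-level correlation matrix.  Latent states of multiple-indicator
constructs, and states at missing single-indicator occasions, are free
parameters updated within the MCMC.

Sampling uses a blocked adaptive Metropolis-within-Gibbs scheme (see
``_sampler``) behind the ``fit`` contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics
from ._transforms import (
    LOG_2PI,
    chol_corr,
    corr_pairs_from_chol,
    half_cauchy_logpdf,
    lkj_chol_log_prior,
    normal_logpdf,
)
from .data import PanelData
from .errors import EstimationError
from .modelspec import ModelSpec, ParameterIndex, parameter_index, person_effect_names

__all__ = [
    "PriorConfig",
    "PosteriorDraws",
    "LogPosterior",
    "log_density",
    "innovation_covariance_reparam",
    "fit",
]


@dataclass
class PriorConfig:
    """Weakly informative (hyper)priors.

    Scales of Cauchy priors are half-Cauchy (truncated at zero).  The
    defaults suit observed variables in a 0-10 range: Normal(0, 4^2) trait
    means, Normal(0, 1) dynamic coefficients, half-Cauchy(0, 1) trait and
    innovation scales, half-Cauchy(0, 0.5) random-effect scales of the phi
    coefficients, LKJ(1) correlation priors, Normal(1, 0.5^2) loadings,
    Normal(0, 10^2) intercepts and half-Cauchy(0, 1) measurement error
    scales.
    """

    trait_mean_scale: float = 4.0
    phi_scale: float = 1.0
    trait_scale_cauchy: float = 1.0
    phi_scale_cauchy: float = 0.5
    lkj_eta: float = 1.0
    innovation_scale_cauchy: float = 1.0
    log_innovation_scale: float = 1.0
    log_innovation_scale_cauchy: float = 1.0
    loading_mean: float = 1.0
    loading_scale: float = 0.5
    intercept_scale: float = 10.0
    measurement_error_cauchy: float = 1.0


def innovation_covariance_reparam(
    ln_sigma2_delta: np.ndarray,
    ln_sigma2_etazeta: np.ndarray | float,
    sign: int = 1,
) -> np.ndarray:
    """Person innovation covariance from common-factor log-parameters.

    ``zeta_q = c_q eta_zeta + delta_q`` yields covariance
    ``[[s2_f + s2_d1, s2_f], [s2_f, s2_f + s2_d2]]`` (for Q = 2, sign +1)
    with all components exp() of the supplied log-variances; positive
    definite for any finite input.
    """
    return dynamics.common_factor_cov(ln_sigma2_delta, ln_sigma2_etazeta, sign)


# ---------------------------------------------------------------------------
# Log posterior
# ---------------------------------------------------------------------------

class LogPosterior:
    """Joint log posterior on an unconstrained parameter vector.

    Layout of ``theta``: global parameters (one slot per entry of
    ``parameter_index``; scales on the log scale, correlations as
    canonical-partial-correlation reals), then person vectors ``z``
    (N x K row-major), then per-construct latent-state blocks (N x T for
    each multiple-indicator construct), then free states at missing
    single-indicator cells.
    """

    def __init__(
        self,
        spec: ModelSpec,
        priors: PriorConfig,
        panel: PanelData,
        initial_state: str = "stationary",
    ):
        spec.validate()
        if initial_state not in ("stationary", "conditional"):
            raise EstimationError(f"unknown initial_state {initial_state!r}")
        self.spec, self.priors = spec, priors
        self.initial_state = initial_state
        self.pidx: ParameterIndex = parameter_index(spec)
        arr = panel.to_arrays(spec)
        self.y = arr["y"]
        self.present = arr["present"]
        self.lag_valid = arr["lag_valid"] & self.present
        self.person_index = arr["person_index"]
        self.N, self.T, self.P = self.y.shape
        self.Q = spec.n_constructs

        # observed-variable column slices per construct
        self.col_slices = []
        start = 0
        for c in spec.constructs:
            self.col_slices.append(slice(start, start + c.n_indicators))
            start += c.n_indicators
        self.single = [c.single_indicator for c in spec.constructs]
        self.factor_qs = [q for q, s in enumerate(self.single) if not s]

        # ---- global index maps --------------------------------------
        names = self.pidx.names
        self.g_idx = {n: i for i, n in enumerate(names)}
        self.G = len(names)
        self.phi_idx = np.array([self.g_idx[t.label] for t in spec.terms], dtype=int)
        self.log_idx = np.array(
            [i for i, e in enumerate(self.pidx.entries) if e.transform == "log"],
            dtype=int,
        )
        self.inncorr_idx = np.array(
            [i for i, e in enumerate(self.pidx.entries) if e.group == "inncorr"],
            dtype=int,
        )
        self.recorr_idx = np.array(
            [i for i, e in enumerate(self.pidx.entries) if e.group == "recorr"],
            dtype=int,
        )
        self.eff_names = person_effect_names(spec)
        self.K = len(self.eff_names)
        gmap, tmap, gsd, tscale = [], [], [], []
        for nm in self.eff_names:
            if nm.startswith("mu_"):
                gmap.append(self.g_idx["gamma_" + nm])
                gsd.append(priors.trait_mean_scale)
                tscale.append(priors.trait_scale_cauchy)
            elif nm.startswith("phi_"):
                gmap.append(self.g_idx[nm])
                gsd.append(priors.phi_scale)
                tscale.append(priors.phi_scale_cauchy)
            else:  # ln_sigma2 components
                gmap.append(self.g_idx["gamma_" + nm])
                gsd.append(priors.log_innovation_scale)
                tscale.append(priors.log_innovation_scale_cauchy)
            tmap.append(self.g_idx["tau_" + nm])
        self.gamma_eff_idx = np.array(gmap, dtype=int)
        self.tau_eff_idx = np.array(tmap, dtype=int)
        self.gamma_eff_prior_sd = np.array(gsd)
        self.tau_eff_cauchy = np.array(tscale)
        if spec.random_innovation_variances:
            self.lnd_eff_pos = [self.eff_names.index(f"ln_sigma2_delta_{q + 1}") for q in range(self.Q)]
            self.lnf_eff_pos = (
                self.eff_names.index("ln_sigma2_etazeta")
                if spec.innovation_covariance == "random"
                else None
            )
        rand_pos = []
        for j, t in enumerate(spec.terms):
            rand_pos.append(self.eff_names.index(t.label) if t.random else -1)
        self.phi_eff_pos = np.array(rand_pos, dtype=int)

        # measurement parameter positions per factor construct
        self.meas_idx = {}
        for q in self.factor_qs:
            c = spec.constructs[q]
            Pq = c.n_indicators
            d = {}
            if c.loadings_free:
                d["lambda_w"] = [self.g_idx[f"lambda_w_{q + 1}_{p + 1}"] for p in range(1, Pq)]
                d["lambda_b"] = [self.g_idx[f"lambda_b_{q + 1}_{p + 1}"] for p in range(1, Pq)]
            d["alpha"] = [self.g_idx[f"alpha_{q + 1}_{p + 1}"] for p in range(1, Pq)]
            d["sigma_eps_w"] = [self.g_idx[f"sigma_eps_w_{q + 1}_{p + 1}"] for p in range(Pq)]
            if spec.between_errors:
                d["sigma_eps_b"] = [self.g_idx[f"sigma_eps_b_{q + 1}_{p + 1}"] for p in range(Pq)]
            self.meas_idx[q] = d

        # ---- latent-state layout ------------------------------------
        self.z_off = self.G
        self.n_z = self.N * self.K
        off = self.z_off + self.n_z
        self.u_off = off
        self.n_u = 0
        if spec.between_errors and self.factor_qs:
            self.n_u = self.N * sum(spec.constructs[q].n_indicators for q in self.factor_qs)
        off += self.n_u
        self.latent_off = {}
        for q in self.factor_qs:
            self.latent_off[q] = off
            off += self.N * self.T
        self.miss_cells = {}
        self.miss_off = {}
        for q in range(self.Q):
            if not self.single[q]:
                continue
            col = self.col_slices[q].start
            mask = self.present & np.isnan(self.y[:, :, col])
            cells = np.argwhere(mask)
            if len(cells):
                self.miss_cells[q] = cells
                self.miss_off[q] = off
                off += len(cells)
        self.dim = off
        self.has_latent = bool(self.factor_qs) or bool(self.miss_cells)

        # observation masks per construct
        self.obs_mask = {}
        for q in range(self.Q):
            self.obs_mask[q] = self.present[:, :, None] & ~np.isnan(self.y[:, :, self.col_slices[q]])
        self.start_mask = self.present & ~self.lag_valid
        self._start_cells = np.argwhere(self.start_mask)
        self._y0 = np.nan_to_num(self.y, nan=0.0)
        self._single_obs = {}
        for q in range(self.Q):
            if self.single[q]:
                self._single_obs[q] = self.obs_mask[q][:, :, 0]
        self._prior_tables()
        self._stat_cache: dict = {}
        self._setup_fast_path()

    def _setup_fast_path(self):
        """Compiled kernel for single-indicator fixed-effects models."""
        from ._fastpath import HAVE_NUMBA

        self.use_fast = (
            HAVE_NUMBA
            and all(self.single)
            and not self.miss_cells
            and not self.spec.has_random_phi
            and not self.spec.random_innovation_variances
        )
        if not self.use_fast:
            return
        cols = [self.col_slices[q].start for q in range(self.Q)]
        y0 = self._y0[:, :, cols].copy()
        obs = np.stack([self._single_obs[q] for q in range(self.Q)], axis=2)
        y0[~obs] = 0.0  # a present-but-missing cell would disable this path
        self._fp_y0 = np.ascontiguousarray(y0)
        terms = self.spec.terms
        self._fp_meta = tuple(
            np.array(v, dtype=np.int64)
            for v in (
                [t.outcome for t in terms],
                [t.predictor for t in terms],
                [t.lag for t in terms],
                [-1 if t.second_predictor is None else t.second_predictor for t in terms],
                [t.second_lag for t in terms],
            )
        )

    def _prior_tables(self):
        """Vectorized prior layout: normal entries and log-scale entries."""
        pr = self.priors
        norm_idx, norm_mu, norm_sd = [], [], []
        hc_idx, hc_scale = [], []
        for i, e in enumerate(self.pidx.entries):
            nm = e.name
            if e.group is not None:
                continue
            if e.category == "phi":
                norm_idx.append(i), norm_mu.append(0.0), norm_sd.append(pr.phi_scale)
            elif nm.startswith("sigma_zeta_"):
                hc_idx.append(i), hc_scale.append(pr.innovation_scale_cauchy)
            elif nm.startswith("gamma_ln_sigma2"):
                norm_idx.append(i), norm_mu.append(0.0), norm_sd.append(pr.log_innovation_scale)
            elif nm.startswith("gamma_mu_"):
                norm_idx.append(i), norm_mu.append(0.0), norm_sd.append(pr.trait_mean_scale)
            elif e.category == "re_scale":
                stem = nm[4:]
                scale = (
                    pr.phi_scale_cauchy
                    if stem.startswith("phi_")
                    else pr.trait_scale_cauchy
                    if stem.startswith("mu_")
                    else pr.log_innovation_scale_cauchy
                )
                hc_idx.append(i), hc_scale.append(scale)
            elif nm.startswith("lambda_"):
                norm_idx.append(i), norm_mu.append(pr.loading_mean), norm_sd.append(pr.loading_scale)
            elif nm.startswith("alpha_"):
                norm_idx.append(i), norm_mu.append(0.0), norm_sd.append(pr.intercept_scale)
            elif nm.startswith("sigma_eps_"):
                hc_idx.append(i), hc_scale.append(pr.measurement_error_cauchy)
        self._norm_idx = np.array(norm_idx, dtype=int)
        self._norm_mu = np.array(norm_mu)
        self._norm_sd = np.array(norm_sd)
        self._hc_idx = np.array(hc_idx, dtype=int)
        self._hc_scale = np.array(hc_scale)

    # ------------------------------------------------------------------
    # unpacking helpers
    # ------------------------------------------------------------------
    def _globals(self, theta):
        g = theta[: self.G]
        key = g.tobytes()
        cached = getattr(self, "_gl_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        out = {"raw": g.copy()}
        out["phi_fix"] = g[self.phi_idx]
        out["gamma_mu"] = np.array([g[self.g_idx[f"gamma_mu_{q + 1}"]] for q in range(self.Q)])
        out["tau_eff"] = np.exp(g[self.tau_eff_idx])
        out["gamma_eff"] = g[self.gamma_eff_idx]
        out["L_re"] = chol_corr(g[self.recorr_idx], self.K) if self.K > 1 else np.eye(1)
        if not self.spec.random_innovation_variances:
            sig = np.exp(
                np.array([g[self.g_idx[f"sigma_zeta_{q + 1}"]] for q in range(self.Q)])
            )
            if self.spec.innovation_covariance == "fixed" and self.Q > 1:
                Lc = chol_corr(g[self.inncorr_idx], self.Q)
                R = Lc @ Lc.T
            else:
                R = np.eye(self.Q)
            out["Sigma_fix"] = R * np.outer(sig, sig)
        meas = {}
        for q in self.factor_qs:
            c = self.spec.constructs[q]
            Pq = c.n_indicators
            d = self.meas_idx[q]
            lam_w = np.ones(Pq)
            lam_b = np.ones(Pq)
            if c.loadings_free:
                lam_w[1:] = g[d["lambda_w"]]
                lam_b[1:] = g[d["lambda_b"]]
            alpha = np.zeros(Pq)
            alpha[1:] = g[d["alpha"]]
            sd_w = np.exp(g[d["sigma_eps_w"]])
            entry = {"lambda_w": lam_w, "lambda_b": lam_b, "alpha": alpha, "sigma_eps_w": sd_w}
            if self.spec.between_errors:
                entry["sigma_eps_b"] = np.exp(g[d["sigma_eps_b"]])
            meas[q] = entry
        out["meas"] = meas
        self._gl_cache = (key, out)
        return out

    def person_effects(self, theta, gl=None):
        gl = gl or self._globals(theta)
        Z = theta[self.z_off : self.z_off + self.n_z].reshape(self.N, self.K)
        E = gl["gamma_eff"] + (Z @ gl["L_re"].T) * gl["tau_eff"]
        return Z, E

    def _latent_eta(self, theta, gl, E):
        """Within-person latent state array (N, T, Q)."""
        eta = np.zeros((self.N, self.T, self.Q))
        for q in range(self.Q):
            if self.single[q]:
                col = self.col_slices[q].start
                eta_q = np.where(
                    self._single_obs[q], self._y0[:, :, col] - E[:, q, None], 0.0
                )
                if q in self.miss_cells:
                    cells = self.miss_cells[q]
                    vals = theta[self.miss_off[q] : self.miss_off[q] + len(cells)]
                    eta_q[cells[:, 0], cells[:, 1]] = vals
                eta[:, :, q] = eta_q
            else:
                o = self.latent_off[q]
                eta[:, :, q] = theta[o : o + self.N * self.T].reshape(self.N, self.T)
        return eta

    def _innovation(self, theta, gl, E):
        """Per-person (or shared) innovation covariance, inverse, logdet."""
        if self.spec.random_innovation_variances:
            ln_d = E[:, self.lnd_eff_pos]
            if self.lnf_eff_pos is not None:
                cov = dynamics.common_factor_cov(
                    ln_d, E[:, self.lnf_eff_pos], self.spec.innovation_covariance_sign
                )
            else:
                cov = np.zeros((self.N, self.Q, self.Q))
                idx = np.arange(self.Q)
                cov[:, idx, idx] = np.exp(ln_d)
            inv = np.linalg.inv(cov)
            _, logdet = np.linalg.slogdet(cov)
            return cov, inv, logdet
        cov = gl["Sigma_fix"]
        inv = np.linalg.inv(cov)
        logdet = float(np.linalg.slogdet(cov)[1])
        return cov, inv, logdet

    def phi_per_person(self, gl, E):
        phi = np.broadcast_to(gl["phi_fix"], (self.N, len(self.spec.terms))).copy()
        for j, pos in enumerate(self.phi_eff_pos):
            if pos >= 0:
                phi[:, j] = E[:, pos]
        return phi

    # ------------------------------------------------------------------
    # density pieces
    # ------------------------------------------------------------------
    def global_prior(self, theta):
        g = theta[: self.G]
        pr = self.priors
        total = 0.0
        if len(self._norm_idx):
            total += float(
                normal_logpdf(g[self._norm_idx], self._norm_mu, self._norm_sd).sum()
            )
        if len(self._hc_idx):
            v = g[self._hc_idx]
            total += float((half_cauchy_logpdf(np.exp(v), self._hc_scale) + v).sum())
        if len(self.inncorr_idx):
            total += lkj_chol_log_prior(g[self.inncorr_idx], self.Q, pr.lkj_eta)
        if len(self.recorr_idx):
            total += lkj_chol_log_prior(g[self.recorr_idx], self.K, pr.lkj_eta)
        return float(total)

    def global_prior_entry(self, i, value):
        """Prior contribution of a single (non-correlation) global entry."""
        e = self.pidx.entries[i]
        pr = self.priors
        nm = e.name
        if e.category == "phi":
            return float(normal_logpdf(value, 0.0, pr.phi_scale))
        if nm.startswith("gamma_mu_"):
            return float(normal_logpdf(value, 0.0, pr.trait_mean_scale))
        if nm.startswith("gamma_ln_sigma2"):
            return float(normal_logpdf(value, 0.0, pr.log_innovation_scale))
        if e.category == "re_scale":
            stem = nm[4:]
            scale = (
                pr.phi_scale_cauchy
                if stem.startswith("phi_")
                else pr.trait_scale_cauchy
                if stem.startswith("mu_")
                else pr.log_innovation_scale_cauchy
            )
            return float(half_cauchy_logpdf(math.exp(value), scale) + value)
        raise EstimationError(f"entry {nm} not supported for single-entry prior")

    def _residuals(self, eta, phi_per):
        """Dynamic residuals (N, T, Q); meaningful only at lag_valid cells."""
        eta_lag = np.zeros_like(eta)
        eta_lag[:, 1:] = eta[:, :-1]
        pred = np.zeros_like(eta)
        for j, t in enumerate(self.spec.terms):
            src = eta_lag if t.lag == 1 else eta
            x = src[:, :, t.predictor]
            if t.second_predictor is not None:
                src2 = eta_lag if t.second_lag == 1 else eta
                x = x * src2[:, :, t.second_predictor]
            pred[:, :, t.outcome] += phi_per[:, j, None] * x
        return eta - pred

    def evaluate(self, theta):
        """Return (global_logp, per-person logp array)."""
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                return self._evaluate(theta)
            except (np.linalg.LinAlgError, FloatingPointError):
                return -np.inf, np.full(self.N, -np.inf)

    def _evaluate(self, theta):
        gl = self._globals(theta)
        if not np.isfinite(gl["tau_eff"]).all():
            return -np.inf, np.full(self.N, -np.inf)
        gp = self.global_prior(theta)
        if not np.isfinite(gp):
            return -np.inf, np.full(self.N, -np.inf)
        Z, E = self.person_effects(theta, gl)

        if self.use_fast:
            plp = self._evaluate_fast(theta, gl, Z, E)
            return gp, plp

        plp = -0.5 * (Z * Z).sum(axis=1) - 0.5 * self.K * LOG_2PI

        cov, inv, logdet = self._innovation(theta, gl, E)
        phi_per = self.phi_per_person(gl, E)
        eta = self._latent_eta(theta, gl, E)

        # measurement likelihood (+ between random effects) for factor constructs
        u_pos = self.u_off
        for q in self.factor_qs:
            m = gl["meas"][q]
            cols = self.col_slices[q]
            Pq = cols.stop - cols.start
            mu_items = m["alpha"][None, :] + m["lambda_b"][None, :] * E[:, q, None]
            if self.spec.between_errors:
                zu = theta[u_pos : u_pos + self.N * Pq].reshape(self.N, Pq)
                u_pos += self.N * Pq
                mu_items = mu_items + zu * m["sigma_eps_b"][None, :]
                plp += -0.5 * (zu * zu).sum(axis=1) - 0.5 * Pq * LOG_2PI
            mean = mu_items[:, None, :] + m["lambda_w"][None, None, :] * eta[:, :, q, None]
            resid = self.y[:, :, cols] - mean
            sd = m["sigma_eps_w"][None, None, :]
            ll = -0.5 * ((resid / sd) ** 2 + LOG_2PI) - np.log(sd)
            plp += np.where(self.obs_mask[q], ll, 0.0).sum(axis=(1, 2))
            # weak anchor on latent states at grid cells that do not exist
            absent = ~self.present
            if absent.any():
                lat = eta[:, :, q]
                anchor = -0.5 * (lat * lat + LOG_2PI)
                plp += np.where(absent, anchor, 0.0).sum(axis=1)

        # dynamic (within-level VAR) likelihood
        resid = self._residuals(eta, phi_per)
        if inv.ndim == 2:
            quad = np.einsum("ntq,qr,ntr->nt", resid, inv, resid)
            ll_t = -0.5 * (quad + self.Q * LOG_2PI + logdet)
        else:
            quad = np.einsum("ntq,nqr,ntr->nt", resid, inv, resid)
            ll_t = -0.5 * (quad + self.Q * LOG_2PI + logdet[:, None])
        plp += np.where(self.lag_valid, ll_t, 0.0).sum(axis=1)

        # initial states at segment starts
        if self.initial_state == "stationary":
            plp += self._initial_logp(eta, phi_per, cov)

        plp = np.where(np.isfinite(plp), plp, -np.inf)
        return gp, plp

    @staticmethod
    def _inv_logdet(S):
        if S.shape[0] == 2:
            det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
            if det <= 0:
                return None, None
            inv = np.array(
                [[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]
            ) / det
            return inv, float(np.log(det))
        try:
            return np.linalg.inv(S), float(np.linalg.slogdet(S)[1])
        except np.linalg.LinAlgError:
            return None, None

    def _fast_precisions(self, phi, cov):
        """(Sigma^-1, log|Sigma|, Sinf^-1, log|Sinf|) with memoization."""
        key = ("fast", phi.tobytes(), cov.tobytes())
        hit = self._stat_cache.get(key)
        if hit is not None:
            return hit
        bad = (None,) * 4
        inv, logdet = self._inv_logdet(cov)
        if inv is None:
            hit = bad
        else:
            A1, A0 = dynamics.linearized_matrices(self.spec, phi[None])
            A1, A0 = A1[0], A0[0]
            Q = self.Q
            if A0.any():
                Binv = np.linalg.inv(np.eye(Q) - A0)
                Phi = Binv @ A1
                Sred = Binv @ cov @ Binv.T
            else:
                Phi, Sred = A1, cov
            if Q == 2:
                tr = Phi[0, 0] + Phi[1, 1]
                det = Phi[0, 0] * Phi[1, 1] - Phi[0, 1] * Phi[1, 0]
                disc = tr * tr - 4.0 * det
                if disc >= 0:
                    r = np.sqrt(disc)
                    rad = max(abs(tr + r), abs(tr - r)) / 2.0
                else:
                    rad = np.sqrt(abs(det))
            else:
                rad = float(np.abs(np.linalg.eigvals(Phi)).max())
            if rad >= 1.0:
                hit = bad
            else:
                M = np.eye(Q * Q) - np.kron(Phi, Phi)
                S = np.linalg.solve(M, Sred.reshape(-1)).reshape(Q, Q)
                Iinv, Ilogdet = self._inv_logdet(S)
                hit = bad if Iinv is None else (inv, logdet, Iinv, Ilogdet)
        if len(self._stat_cache) > 64:
            self._stat_cache.clear()
        self._stat_cache[key] = hit
        return hit

    def _evaluate_fast(self, theta, gl, Z, E):
        from ._fastpath import person_logp_single

        cov = gl["Sigma_fix"]
        phi = gl["phi_fix"]
        use_init = self.initial_state == "stationary"
        if use_init:
            inv, logdet, Iinv, Ilogdet = self._fast_precisions(phi, cov)
            if inv is None:
                return np.full(self.N, -np.inf)
        else:
            inv, logdet = self._inv_logdet(cov)
            if inv is None:
                return np.full(self.N, -np.inf)
            Iinv, Ilogdet = np.eye(self.Q), 0.0
        plp = person_logp_single(
            self._fp_y0,
            self.present,
            self.lag_valid,
            Z,
            E,
            phi,
            *self._fp_meta,
            inv,
            logdet,
            Iinv,
            Ilogdet,
            use_init,
            LOG_2PI,
        )
        return np.where(np.isfinite(plp), plp, -np.inf)

    def _stationary_covs(self, phi_per, cov):
        """Linearized stationary covariance per person (NaN if unstable)."""
        if self.spec.has_random_phi or cov.ndim == 3:
            covs = cov if cov.ndim == 3 else np.broadcast_to(cov, (self.N, self.Q, self.Q))
            return dynamics.stationary_cov_linear(self.spec, phi_per, covs)
        S = dynamics.stationary_cov_linear(self.spec, phi_per[:1], cov[None])[0]
        return np.broadcast_to(S, (self.N, self.Q, self.Q))

    def _initial_logp(self, eta, phi_per, cov):
        """Stationary-prior contribution of segment-start states.

        The shared-parameter case (no random phi, shared innovation
        covariance) is memoized on the parameter bytes, since most sampler
        moves leave the dynamic parameters untouched.
        """
        cells = self._start_cells
        out = np.zeros(self.N)
        shared = not self.spec.has_random_phi and cov.ndim == 2
        if shared:
            key = ("slow", phi_per[0].tobytes(), cov.tobytes())
            hit = self._stat_cache.get(key)
            if hit is None:
                S = dynamics.stationary_cov_linear(self.spec, phi_per[:1], cov[None])[0]
                if not np.isfinite(S).all():
                    hit = (None, None)
                else:
                    hit = (np.linalg.inv(S), float(np.linalg.slogdet(S)[1]))
                if len(self._stat_cache) > 16:
                    self._stat_cache.clear()
                self._stat_cache[key] = hit
            inv, logdet = hit
            if inv is None:
                return np.full(self.N, -np.inf)
            x = eta[cells[:, 0], cells[:, 1]]  # (M, Q)
            quad = np.einsum("mq,qr,mr->m", x, inv, x)
            ll = -0.5 * (quad + self.Q * LOG_2PI + logdet)
            np.add.at(out, cells[:, 0], ll)
            return out
        S = self._stationary_covs(phi_per, cov)
        bad = ~np.isfinite(S).all(axis=(1, 2))
        ok_cells = cells[~bad[cells[:, 0]]]
        if len(ok_cells):
            Sm = S[ok_cells[:, 0]]
            inv = np.linalg.inv(Sm)
            _, logdet = np.linalg.slogdet(Sm)
            x = eta[ok_cells[:, 0], ok_cells[:, 1]]
            quad = np.einsum("mq,mqr,mr->m", x, inv, x)
            ll = -0.5 * (quad + self.Q * LOG_2PI + logdet)
            np.add.at(out, ok_cells[:, 0], ll)
        out[bad] = -np.inf
        return out

    # ------------------------------------------------------------------
    # packing / initialization
    # ------------------------------------------------------------------
    def pack(self, globals_constrained: dict, Z=None, latent=None, miss=None):
        """Build a theta vector from readable pieces.

        ``globals_constrained`` maps parameter-table names to values on
        the reporting scale (scales as SDs); correlation groups are given
        directly as unconstrained vectors under ``z_inncorr`` /
        ``z_recorr``.  ``latent`` maps factor construct index -> (N, T)
        state array; ``miss`` maps single construct index -> vector.
        """
        theta = np.zeros(self.dim)
        for i, e in enumerate(self.pidx.entries):
            if e.group is not None:
                continue
            v = globals_constrained[e.name]
            theta[i] = math.log(v) if e.transform == "log" else v
        if len(self.inncorr_idx):
            theta[self.inncorr_idx] = globals_constrained.get(
                "z_inncorr", np.zeros(len(self.inncorr_idx))
            )
        if len(self.recorr_idx):
            theta[self.recorr_idx] = globals_constrained.get(
                "z_recorr", np.zeros(len(self.recorr_idx))
            )
        if Z is not None:
            theta[self.z_off : self.z_off + self.n_z] = np.asarray(Z).reshape(-1)
        if latent:
            for q, block in latent.items():
                o = self.latent_off[q]
                theta[o : o + self.N * self.T] = np.asarray(block).reshape(-1)
        if miss:
            for q, vals in miss.items():
                o = self.miss_off[q]
                theta[o : o + len(vals)] = vals
        return theta

    def initial_theta(self, rng: np.random.Generator, jitter: float = 1.0):
        """Data-informed starting point with per-chain jitter."""
        gc = {}
        person_means = np.zeros((self.N, self.Q))
        within_sd = np.zeros(self.Q)
        for q in range(self.Q):
            cols = self.col_slices[q]
            yq = self.y[:, :, cols]
            with np.errstate(invalid="ignore"):
                pm = np.nanmean(np.where(self.obs_mask[q], yq, np.nan), axis=(1, 2))
            pm = np.where(np.isfinite(pm), pm, np.nanmean(yq))
            person_means[:, q] = pm
            centered = yq[:, :, 0] - pm[:, None]
            within_sd[q] = max(float(np.nanstd(centered)), 1e-2)
        j = lambda s: jitter * s * rng.standard_normal()

        for i, e in enumerate(self.pidx.entries):
            nm = e.name
            if e.group is not None:
                gc[nm] = 0.0
                continue
            if e.category == "phi":
                gc[nm] = 0.1 + j(0.05)
            elif nm.startswith("sigma_zeta_"):
                q = int(nm.rsplit("_", 1)[1]) - 1
                gc[nm] = within_sd[q] * (0.85 + abs(j(0.1)))
            elif nm.startswith("gamma_ln_sigma2_delta"):
                q = int(nm.rsplit("_", 1)[1]) - 1
                gc[nm] = 2 * math.log(max(within_sd[q] * 0.8, 1e-2)) + j(0.2)
            elif nm == "gamma_ln_sigma2_etazeta":
                gc[nm] = -1.5 + j(0.2)
            elif nm.startswith("gamma_mu_"):
                q = int(nm.rsplit("_", 1)[1]) - 1
                gc[nm] = float(person_means[:, q].mean()) + j(0.1)
            elif nm.startswith("tau_mu_"):
                q = int(nm[7:]) - 1
                gc[nm] = max(float(person_means[:, q].std()), 0.05) * (1 + j(0.1))
            elif nm.startswith("tau_phi"):
                gc[nm] = 0.1 * (1 + abs(j(0.3)))
            elif nm.startswith("tau_ln_sigma2"):
                gc[nm] = 0.3 * (1 + abs(j(0.3)))
            elif nm.startswith("lambda_"):
                gc[nm] = 1.0 + j(0.1)
            elif nm.startswith("alpha_"):
                gc[nm] = 0.0 + j(0.1)
            elif nm.startswith("sigma_eps_"):
                gc[nm] = 0.5 * (1 + abs(j(0.2)))
        theta = self.pack(gc)
        # person z: traits from person means, other effects near zero
        Z = 0.1 * jitter * rng.standard_normal((self.N, self.K))
        for q in range(self.Q):
            tau = gc[f"tau_mu_{q + 1}"]
            Z[:, q] = np.clip(
                (person_means[:, q] - gc[f"gamma_mu_{q + 1}"]) / max(tau, 1e-3), -3, 3
            )
        theta[self.z_off : self.z_off + self.n_z] = Z.reshape(-1)
        # latent states from the first (centered) indicator
        for q in self.factor_qs:
            cols = self.col_slices[q]
            lat = self.y[:, :, cols.start] - person_means[:, q, None]
            lat = np.nan_to_num(np.where(self.present, lat, 0.0), nan=0.0)
            o = self.latent_off[q]
            theta[o : o + self.N * self.T] = lat.reshape(-1)
        return theta

    # ------------------------------------------------------------------
    # reporting-scale conversion
    # ------------------------------------------------------------------
    def constrain(self, g_draws: np.ndarray) -> np.ndarray:
        """Map unconstrained global draws (S, G) to the reporting scale."""
        out = np.array(g_draws[:, : self.G], dtype=float)
        if len(self.log_idx):
            out[:, self.log_idx] = np.exp(out[:, self.log_idx])
        for idx, d in ((self.inncorr_idx, self.Q), (self.recorr_idx, self.K)):
            if len(idx):
                for s in range(out.shape[0]):
                    out[s, idx] = corr_pairs_from_chol(chol_corr(g_draws[s, idx], d))
        return out


def log_density(spec, priors, data, params, initial_state="stationary") -> float:
    """Joint log posterior density at an unconstrained parameter vector."""
    lp = LogPosterior(spec, priors, data, initial_state=initial_state)
    g, p = lp.evaluate(np.asarray(params, dtype=float))
    return float(g + p.sum())


# ---------------------------------------------------------------------------
# Posterior draws container and fit
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Post-warm-up draws plus convergence diagnostics.

    ``draws`` has shape (chains, samples, parameters) on the reporting
    scale, columns ordered as ``names`` (the model's parameter table).
    ``person_draws`` optionally stores per-person effect draws (chains,
    samples, N, K) for random-effect summaries.
    """

    draws: np.ndarray
    names: list
    rhat: np.ndarray
    ess_bulk: np.ndarray
    ess_tail: np.ndarray
    n_divergent: np.ndarray
    person_draws: np.ndarray | None = None
    person_effect_names: list = field(default_factory=list)
    person_index: np.ndarray | None = None
    n_iterations: int = 0

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def mean(self) -> np.ndarray:
        return self.flat().mean(axis=0)

    def ci(self, level: float = 0.95) -> np.ndarray:
        a = (1 - level) / 2
        return np.quantile(self.flat(), [a, 1 - a], axis=0)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame(
            {
                "mean": self.mean(),
                "q2.5": lo,
                "q97.5": hi,
                "rhat": self.rhat,
                "ess_bulk": self.ess_bulk,
                "ess_tail": self.ess_tail,
            },
            index=pd.Index(self.names, name="parameter"),
        )

    def to_csv(self, path) -> None:
        flat = self.flat()
        C, S, _ = self.draws.shape
        df = pd.DataFrame(flat, columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(C), S))
        df.insert(1, "iteration", np.tile(np.arange(S), C))
        df.to_csv(path, index=False)


def _compute_diagnostics(draws: np.ndarray, names: list):
    """Rank-normalized split-Rhat and bulk/tail ESS via arviz.

    A single variable with a parameter dimension keeps the computation
    vectorized across parameters.
    """
    import arviz as az

    ds = az.convert_to_dataset({"theta": draws})
    rhat = np.asarray(az.rhat(ds)["theta"].values, dtype=float)
    essb = np.asarray(az.ess(ds, method="bulk")["theta"].values, dtype=float)
    esst = np.asarray(az.ess(ds, method="tail")["theta"].values, dtype=float)
    return rhat, essb, esst


def fit(
    spec: ModelSpec,
    priors: PriorConfig | None,
    data: PanelData,
    chains: int = 2,
    iterations: int = 4000,
    seed: int = 0,
    initial_state: str = "stationary",
    store_person_draws: bool = True,
) -> PosteriorDraws:
    """Sample the posterior with the blocked adaptive MCMC sampler.

    ``iterations`` is the total per-chain length; the first half is
    warm-up (used for proposal adaptation) and discarded.  Reproducible
    given ``seed``; chains use independent derived seeds.
    """
    from ._sampler import run_chain

    if chains < 2:
        raise EstimationError("at least 2 chains are required for Rhat/ESS")
    priors = priors or PriorConfig()
    lp = LogPosterior(spec, priors, data, initial_state=initial_state)
    for q in range(lp.Q):
        yq = lp.y[:, :, lp.col_slices[q]]
        vals = yq[lp.obs_mask[q]]
        if len(vals) == 0 or float(np.nanstd(vals)) < 1e-10:
            raise EstimationError(
                f"observed data for construct {spec.constructs[q].name!r} are "
                "degenerate (no variance); estimation would be meaningless"
            )

    warmup = iterations // 2
    keep = iterations - warmup
    g_draws = np.empty((chains, keep, lp.G))
    p_draws = (
        np.empty((chains, keep, lp.N, lp.K)) if store_person_draws else None
    )
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        theta_draws = run_chain(lp, iterations, warmup, rng)
        g_draws[c] = lp.constrain(theta_draws[:, : lp.G])
        if store_person_draws:
            for s in range(keep):
                gl = lp._globals(theta_draws[s])
                _, E = lp.person_effects(theta_draws[s], gl)
                p_draws[c, s] = E

    rhat, essb, esst = _compute_diagnostics(g_draws, lp.pidx.names)
    return PosteriorDraws(
        draws=g_draws,
        names=lp.pidx.names,
        rhat=rhat,
        ess_bulk=essb,
        ess_tail=esst,
        n_divergent=np.zeros(chains, dtype=int),
        person_draws=p_draws,
        person_effect_names=lp.eff_names,
        person_index=lp.person_index,
        n_iterations=iterations,
    )
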