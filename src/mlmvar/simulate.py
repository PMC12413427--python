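"""Synthetic multilevel intensive-longitudinal data.

Generation mirrors the estimation model: person-specific parameters are
drawn from a between-level multivariate normal (log-normal for innovation
variance components), each person's latent within-person series follows
the moderated VAR recursion from a zero initial state with a long burn-in
discarded, and observations add the measurement layer on top.  Draws
whose implied dynamics are not locally stationary are rejected and
replaced, so that every generated series is well behaved.

Default generating values: AR fixed effects 0.3-0.4, CR magnitudes
0.1-0.25, interaction magnitudes 0.05-0.2, random-effect variances of the
phi coefficients 0.01, log innovation variances -0.5 (or -0.7 with a
common-factor component of -1.3) with random-effect variance 0.2, factor
loadings 1 with within-level measurement error variance 0.3 (item
reliabilities around .72), trait correlation 0.3, and trait means/scales
that keep observed values in a 0-10 range with intra-class correlations
of 0.4-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import dynamics
from .data import PanelData
from .errors import ConfigurationError
from .io import GridTemplate
from .modelspec import ModelSpec, parameter_index, person_effect_names

__all__ = [
    "GenConfig",
    "PersonParams",
    "default_gen_config",
    "draw_person_params",
    "check_stationarity",
    "simulate_person_series",
    "emit_observations",
    "simulate_dataset",
]


@dataclass
class GenConfig:
    """Data-generating parameter values and sample sizes.

    All structural values are keyed the same way as the estimator's
    parameter table, so a config doubles as the truth for recovery
    scoring (see :meth:`truth_vector`).
    """

    n_persons: int = 100
    n_times: int = 50
    fixed_effects: dict = field(default_factory=dict)  # phi label -> value
    trait_means: list = field(default_factory=list)  # gamma_mu per construct
    trait_sds: list = field(default_factory=list)  # tau_mu per construct
    trait_corr: float = 0.3
    phi_sd: float = 0.1  # tau for random phi terms (tau^2 = 0.01)
    ln_sigma2_delta: list = field(default_factory=list)
    ln_sigma2_etazeta: float = -1.3
    tau_ln_sigma2: float = 0.0  # sqrt(0.2) in random-innovation models
    innovation_corr: float = 0.3  # fixed innovation covariance variant
    re_corr: np.ndarray | None = None  # full between-level correlation matrix
    lambda_w: float = 1.0
    lambda_b: float = 1.0
    within_error_var: float = 0.3
    between_error_var: float = 0.0
    observed_error_var: list = field(default_factory=list)  # single-indicator noise
    burn_in: int = 500
    missing_rate: float = 0.0
    grid: GridTemplate | None = None
    stationarity_bound: float = 1e3
    max_rejections: int = 500

    # ------------------------------------------------------------------
    def resolved(self, spec: ModelSpec) -> "GenConfig":
        """Fill per-construct defaults that depend on the model structure."""
        Q = spec.n_constructs
        cfg = replace(self)
        if not cfg.trait_means:
            cfg.trait_means = [5.0] * Q
        if not cfg.trait_sds:
            cfg.trait_sds = [0.95 if spec.any_factor else 0.8] * Q
        if not cfg.ln_sigma2_delta:
            base = -0.7 if spec.innovation_covariance == "random" else -0.5
            cfg.ln_sigma2_delta = [base] * Q
        if not cfg.observed_error_var:
            cfg.observed_error_var = [0.0] * Q
        if spec.random_innovation_variances and cfg.tau_ln_sigma2 == 0.0:
            cfg.tau_ln_sigma2 = float(np.sqrt(0.2))
        if cfg.re_corr is None:
            eff = person_effect_names(spec)
            K = len(eff)
            R = np.eye(K)
            for a in range(Q):
                for b in range(Q):
                    if a != b:
                        R[a, b] = cfg.trait_corr
            cfg.re_corr = R
        return cfg

    def validate(self, spec: ModelSpec) -> None:
        cfg = self.resolved(spec)
        for t in spec.terms:
            if t.label not in cfg.fixed_effects:
                raise ConfigurationError(f"no generating value for {t.label}")
        if any(s < 0 for s in cfg.trait_sds) or cfg.phi_sd < 0 or cfg.tau_ln_sigma2 < 0:
            raise ConfigurationError("variance parameters must be >= 0")
        R = np.asarray(cfg.re_corr)
        if R.shape[0] != len(person_effect_names(spec)):
            raise ConfigurationError("re_corr has wrong dimension")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ConfigurationError("re_corr must be positive definite")

    # ------------------------------------------------------------------
    def effect_means_sds(self, spec: ModelSpec):
        """Means and SDs of the person-effect vector, in canonical order."""
        cfg = self.resolved(spec)
        means, sds = [], []
        for q in range(spec.n_constructs):
            means.append(cfg.trait_means[q])
            sds.append(cfg.trait_sds[q])
        for t in spec.terms:
            if t.random:
                means.append(cfg.fixed_effects[t.label])
                sds.append(cfg.phi_sd)
        if spec.random_innovation_variances:
            for q in range(spec.n_constructs):
                means.append(cfg.ln_sigma2_delta[q])
                sds.append(cfg.tau_ln_sigma2)
            if spec.innovation_covariance == "random":
                means.append(cfg.ln_sigma2_etazeta)
                sds.append(cfg.tau_ln_sigma2)
        return np.array(means), np.array(sds)

    def fixed_innovation_cov(self, spec: ModelSpec) -> np.ndarray:
        cfg = self.resolved(spec)
        Q = spec.n_constructs
        var = np.exp(np.asarray(cfg.ln_sigma2_delta))
        cov = np.diag(var)
        if spec.innovation_covariance == "fixed":
            sd = np.sqrt(var)
            for a in range(Q):
                for b in range(Q):
                    if a != b:
                        cov[a, b] = cfg.innovation_corr * sd[a] * sd[b]
        return cov

    def truth_vector(self, spec: ModelSpec) -> dict:
        """Generating value for every entry of the model's parameter table."""
        cfg = self.resolved(spec)
        pidx = parameter_index(spec)
        eff = person_effect_names(spec)
        means, sds = self.effect_means_sds(spec)
        R = np.asarray(cfg.re_corr)
        out = {}
        for entry in pidx.entries:
            nm = entry.name
            if nm in cfg.fixed_effects:
                out[nm] = cfg.fixed_effects[nm]
            elif nm.startswith("sigma_zeta_"):
                q = int(nm.rsplit("_", 1)[1]) - 1
                out[nm] = float(np.exp(cfg.ln_sigma2_delta[q] / 2))
            elif nm.startswith("r_zeta") or (nm.startswith("rho(zeta")):
                out[nm] = cfg.innovation_corr
            elif nm.startswith("gamma_ln_sigma2_delta_"):
                q = int(nm.rsplit("_", 1)[1]) - 1
                out[nm] = cfg.ln_sigma2_delta[q]
            elif nm == "gamma_ln_sigma2_etazeta":
                out[nm] = cfg.ln_sigma2_etazeta
            elif nm.startswith("gamma_mu_"):
                q = int(nm.rsplit("_", 1)[1]) - 1
                out[nm] = cfg.trait_means[q]
            elif nm.startswith("tau_"):
                stem = nm[4:]
                out[nm] = float(sds[eff.index(stem)])
            elif nm.startswith("rho("):
                a, b = nm[4:-1].split(",")
                if a.startswith("zeta"):
                    out[nm] = cfg.innovation_corr
                else:
                    out[nm] = float(R[eff.index(a), eff.index(b)])
            elif nm.startswith("lambda_w") or nm.startswith("lambda_b"):
                out[nm] = cfg.lambda_w if "w" in nm.split("_")[1] else cfg.lambda_b
            elif nm.startswith("alpha_"):
                out[nm] = 0.0
            elif nm.startswith("sigma_eps_w"):
                q = int(nm.split("_")[3]) - 1
                out[nm] = float(np.sqrt(_per_construct(cfg.within_error_var, q)))
            elif nm.startswith("sigma_eps_b"):
                out[nm] = float(np.sqrt(cfg.between_error_var))
            else:  # pragma: no cover - defensive
                raise ConfigurationError(f"no generating value for parameter {nm}")
        return out


def _per_construct(value, q: int) -> float:
    """Scalar config values apply to every construct; lists are per construct."""
    if isinstance(value, (list, tuple, np.ndarray)):
        return float(value[q])
    return float(value)


_DEFAULT_PHI = {
    "A": {"phi_11": 0.35, "phi_21": 0.15, "phi_22": 0.3, "phi_2.12": 0.1},
    "B": {
        "phi_11": 0.35,
        "phi_12": 0.1,
        "phi_1.12": 0.05,
        "phi_21": 0.15,
        "phi_22": 0.3,
        "phi_2.12": 0.1,
    },
    "C": {
        "phi_11": 0.35,
        "phi_21": -0.15,
        "phi_22": 0.3,
        "phi_23": 0.25,
        "phi_2.13": -0.12,
        "phi_2.12": 0.08,
        "phi_31": -0.1,
        "phi_32": 0.15,
        "phi_33": 0.3,
        "phi_3.13": -0.08,
        "phi_3.12": 0.05,
    },
    "ex2": {
        "phi_11": 0.35,
        "phi_12": 0.1,
        "phi_21": 0.25,
        "phi_22": 0.3,
        "phi_2.12": 0.1,
    },
}


def default_gen_config(spec: ModelSpec, **overrides) -> GenConfig:
    """Generating configuration with the canonical study conditions."""
    fx = overrides.pop("fixed_effects", None)
    if fx is None:
        fx = dict(_DEFAULT_PHI.get(spec.name, {}))
        if not fx:
            raise ConfigurationError(
                "no default fixed effects for a custom spec; pass fixed_effects="
            )
    cfg = GenConfig(fixed_effects=fx, **overrides)
    cfg = cfg.resolved(spec)
    cfg.validate(spec)
    return cfg


# ---------------------------------------------------------------------------
# Person-level parameters
# ---------------------------------------------------------------------------

@dataclass
class PersonParams:
    """Realized parameters for one person."""

    phi: np.ndarray  # one value per spec term
    innovation_cov: np.ndarray  # (Q, Q), positive definite
    mu: np.ndarray  # latent trait values, one per construct
    ln_sigma2_delta: np.ndarray | None = None
    ln_sigma2_etazeta: float | None = None
    rejections: int = 0


def _person_from_effects(cfg: GenConfig, spec: ModelSpec, effects: np.ndarray) -> PersonParams:
    Q = spec.n_constructs
    mu = effects[:Q]
    pos = Q
    phi = np.empty(len(spec.terms))
    for j, t in enumerate(spec.terms):
        if t.random:
            phi[j] = effects[pos]
            pos += 1
        else:
            phi[j] = cfg.fixed_effects[t.label]
    if spec.random_innovation_variances:
        ln_d = effects[pos:pos + Q]
        pos += Q
        if spec.innovation_covariance == "random":
            ln_f = float(effects[pos])
            cov = dynamics.common_factor_cov(ln_d, ln_f, spec.innovation_covariance_sign)[0]
        else:
            ln_f = None
            cov = np.diag(np.exp(ln_d))
        return PersonParams(phi, cov, mu, ln_d, ln_f)
    return PersonParams(phi, cfg.fixed_innovation_cov(spec), mu)


def check_stationarity(
    pp: PersonParams,
    spec: ModelSpec,
    cfg: GenConfig,
    rng: np.random.Generator | None = None,
):
    """Local-stationarity screen for one person's parameters.

    Passes iff (a) every AR coefficient is inside (-1, 1), (b) the
    linearized (interaction-at-zero) reduced-form transition matrix has
    spectral radius < 1, and (c) a screening simulation of burn_in +
    n_times steps stays finite and inside ``cfg.stationarity_bound``.
    Returns (ok, diagnostics).
    """
    cfg = cfg.resolved(spec)
    diag = {}
    ar_ok = True
    for j, t in enumerate(spec.terms):
        if t.kind == "AR" and not (-1.0 < pp.phi[j] < 1.0):
            ar_ok = False
    diag["ar_in_range"] = ar_ok
    rad = float(dynamics.companion_spectral_radius(spec, pp.phi[None])[0])
    diag["spectral_radius"] = rad
    if not ar_ok or rad >= 1.0:
        return False, diag
    rng = rng or np.random.default_rng(0)
    chol = np.linalg.cholesky(pp.innovation_cov)[None]
    mom = dynamics.simulate_moments(
        spec, pp.phi[None], chol, cfg.n_times, cfg.burn_in, rng,
        bound=cfg.stationarity_bound,
    )
    diag["screen_finite"] = bool(mom["finite"][0])
    return bool(mom["finite"][0]), diag


def draw_person_params(
    cfg: GenConfig, spec: ModelSpec, rng: np.random.Generator
) -> PersonParams:
    """Draw one person's parameters, rejection-resampling non-stationary draws."""
    cfg = cfg.resolved(spec)
    means, sds = cfg.effect_means_sds(spec)
    L = np.linalg.cholesky(np.asarray(cfg.re_corr))
    rejections = 0
    while True:
        z = rng.standard_normal(len(means))
        effects = means + sds * (L @ z)
        pp = _person_from_effects(cfg, spec, effects)
        ok, _ = check_stationarity(pp, spec, cfg, rng)
        if ok:
            pp.rejections = rejections
            return pp
        rejections += 1
        if rejections >= cfg.max_rejections:
            raise ConfigurationError(
                "generating values incompatible with local stationarity "
                f"({rejections} consecutive rejected draws)"
            )


def simulate_person_series(
    pp: PersonParams,
    spec: ModelSpec,
    T: int,
    burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent within-person series (T, Q) for one person."""
    chol = np.linalg.cholesky(pp.innovation_cov)[None]
    return dynamics.simulate_series(spec, pp.phi[None], chol, T, burn_in, rng)[0]


# ---------------------------------------------------------------------------
# Observation layer
# ---------------------------------------------------------------------------

def emit_observations(
    latent: np.ndarray,
    pps: list[PersonParams],
    cfg: GenConfig,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Map latent series (N, T, Q) to observed indicators (N, T, P).

    Single-indicator constructs: y = mu_i + eta (+ optional observation
    noise, the lever for reliability conditions estimated without a
    measurement model).  Factor constructs: y_p = alpha_p + lambda_B,p *
    mu_i + u_ip + lambda_W,p * eta + eps with iid normal measurement
    residuals.
    """
    cfg = cfg.resolved(spec)
    N, T, Q = latent.shape
    mu = np.stack([pp.mu for pp in pps])  # (N, Q)
    cols = []
    for q, c in enumerate(spec.constructs):
        eta = latent[:, :, q]
        if c.single_indicator:
            y = mu[:, q, None] + eta
            ev = cfg.observed_error_var[q]
            if ev > 0:
                y = y + rng.normal(0.0, np.sqrt(ev), size=y.shape)
            cols.append(y[:, :, None])
        else:
            P = c.n_indicators
            u = np.zeros((N, P))
            if cfg.between_error_var > 0:
                u = rng.normal(0.0, np.sqrt(cfg.between_error_var), size=(N, P))
            mu_items = cfg.lambda_b * mu[:, q, None] + u  # alpha = 0 by default
            wev = _per_construct(cfg.within_error_var, q)
            eps = rng.normal(0.0, np.sqrt(wev), size=(N, T, P))
            y = mu_items[:, None, :] + cfg.lambda_w * eta[:, :, None] + eps
            cols.append(y)
    return np.concatenate(cols, axis=2)


def simulate_dataset(
    cfg: GenConfig,
    spec: ModelSpec,
    rng: np.random.Generator | int,
) -> PanelData:
    """Generate a complete panel (plus stored truth) for all persons."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    spec.validate()
    cfg = cfg.resolved(spec)
    cfg.validate(spec)
    if cfg.grid is not None and cfg.grid.n_occasions != cfg.n_times:
        raise ConfigurationError("grid template size must equal n_times")

    pps = [draw_person_params(cfg, spec, rng) for _ in range(cfg.n_persons)]
    phi = np.stack([pp.phi for pp in pps])
    chol = np.linalg.cholesky(np.stack([pp.innovation_cov for pp in pps]))
    latent = dynamics.simulate_series(spec, phi, chol, cfg.n_times, cfg.burn_in, rng)
    y = emit_observations(latent, pps, cfg, spec, rng)

    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n_persons, cfg.n_times)) < cfg.missing_rate
        y[mask] = np.nan

    if cfg.grid is not None:
        lv_row = cfg.grid.lag_valid_template()
        day = cfg.grid.day_of_occasion()
    else:
        lv_row = np.ones(cfg.n_times, dtype=bool)
        lv_row[0] = False
        day = np.zeros(cfg.n_times, dtype=int)
    lag_valid = np.broadcast_to(lv_row, (cfg.n_persons, cfg.n_times)).copy()

    truth = {
        "eta_w": latent,
        "mu": np.stack([pp.mu for pp in pps]),
        "person_params": pps,
        "truth_vector": cfg.truth_vector(spec),
        "rejections": int(sum(pp.rejections for pp in pps)),
    }
    return PanelData.from_arrays(spec, y, lag_valid, day=day, latent_truth=truth)
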