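"""Standardization, interaction surfaces, variance explained, reliabilities."""

import numpy as np
import pandas as pd
import pytest

import mlmvar as m
from mlmvar import dynamics
from mlmvar.errors import ConfigurationError
from mlmvar.modelspec import ConstructDef, LagTerm, ModelSpec, parameter_index
from mlmvar.posterior import PosteriorDraws
from mlmvar.postprocess import StandardizedDraws, _fixed_effect_batches


def make_draws(spec, values, n=40, jitter=0.0, seed=0):
    """PosteriorDraws with chosen values (optionally jittered across draws)."""
    pidx = parameter_index(spec)
    rng = np.random.default_rng(seed)
    G = pidx.size
    base = np.array([values[nm] for nm in pidx.names])
    flat = base[None, :] + jitter * rng.standard_normal((n, G))
    draws = flat.reshape(2, n // 2, G)
    return PosteriorDraws(
        draws=draws,
        names=pidx.names,
        rhat=np.ones(G),
        ess_bulk=np.full(G, 1e4),
        ess_tail=np.full(G, 1e4),
        n_divergent=np.zeros(2, dtype=int),
    )


def crossed_var_spec():
    """Interaction-free 2-construct VAR (closed-form moments exist)."""
    return ModelSpec(
        constructs=[ConstructDef("a"), ConstructDef("b")],
        terms=[LagTerm(0, 0, "AR"), LagTerm(1, 0, "CR"), LagTerm(1, 1, "AR")],
        name="var2",
    )


def var2_values(phi11=0.4, phi21=0.2, phi22=0.3, s1=0.8, s2=0.7):
    return {
        "phi_11": phi11, "phi_21": phi21, "phi_22": phi22,
        "sigma_zeta_1": s1, "sigma_zeta_2": s2,
        "gamma_mu_1": 5.0, "gamma_mu_2": 5.0,
        "tau_mu_1": 0.8, "tau_mu_2": 0.8, "rho(mu_1,mu_2)": 0.3,
    }


MODEL_A_VALUES = {
    "phi_11": 0.35, "phi_21": 0.15, "phi_22": 0.3, "phi_2.12": 0.1,
    "sigma_zeta_1": 0.78, "sigma_zeta_2": 0.78,
    "gamma_mu_1": 5.0, "gamma_mu_2": 5.0,
    "tau_mu_1": 0.8, "tau_mu_2": 0.8, "rho(mu_1,mu_2)": 0.3,
}


class TestStandardize:
    def test_closed_form_crossed_var(self):
        spec = crossed_var_spec()
        draws = make_draws(spec, var2_values(), n=4)
        std = m.standardize(draws, spec)
        S = dynamics.stationary_cov_linear(
            spec,
            np.array([[0.4, 0.2, 0.3]]),
            np.diag([0.8**2, 0.7**2])[None],
        )[0]
        sd = np.sqrt(np.diag(S))
        expect_cr = 0.2 * sd[0] / sd[1]
        assert np.allclose(std.coefs[:, 1], expect_cr, atol=1e-10)
        # AR effects invariant under within-person standardization
        assert np.allclose(std.coefs[:, 0], 0.4)
        assert np.allclose(std.coefs[:, 2], 0.3)

    def test_interaction_model_matches_bruteforce_sds(self, spec_a):
        draws = make_draws(spec_a, MODEL_A_VALUES, n=4)
        std = m.standardize(draws, spec_a, n_steps=200_000, seed=5)
        # independent long simulation of the same recursion
        phi = np.array([[0.35, 0.15, 0.3, 0.1]])
        chol = np.linalg.cholesky(np.diag([0.78**2, 0.78**2]))[None]
        eta = dynamics.simulate_series(
            spec_a, phi, chol, 150_000, 500, np.random.default_rng(77)
        )[0]
        sd1, sd2 = eta.std(axis=0)
        sd_prod = (eta[:-1, 0] * eta[:-1, 1]).std()
        expect = {
            "phi_11": 0.35,
            "phi_21": 0.15 * sd1 / sd2,
            "phi_22": 0.3,
            "phi_2.12": 0.1 * sd_prod / sd2,
        }
        got = dict(zip(std.term_labels, std.coefs.mean(axis=0)))
        for nm, v in expect.items():
            assert got[nm] == pytest.approx(v, rel=0.02), nm

    def test_sign_preserved_and_ar_unchanged(self, spec_a):
        vals = dict(MODEL_A_VALUES, **{"phi_21": -0.2, "phi_2.12": -0.08})
        draws = make_draws(spec_a, vals, n=6, jitter=0.0)
        std = m.standardize(draws, spec_a, n_steps=30_000)
        got = dict(zip(std.term_labels, std.coefs.mean(axis=0)))
        assert got["phi_21"] < 0 and got["phi_2.12"] < 0
        assert got["phi_11"] == pytest.approx(0.35)

    def test_nonstationary_draws_excluded_with_count(self, spec_a):
        vals = dict(MODEL_A_VALUES, phi_11=1.3)
        draws = make_draws(spec_a, vals, n=4)
        std = m.standardize(draws, spec_a, n_steps=5_000)
        assert std.n_excluded == 4
        assert std.coefs.shape[0] == 0


class TestSimpleSlopes:
    def _std(self, cr, inter, n=500, sd=0.0, seed=1):
        rng = np.random.default_rng(seed)
        coefs = np.column_stack(
            [
                np.full(n, 0.35),  # phi_11 (AR of moderator)
                cr + sd * rng.standard_normal(n),  # phi_21 CR
                np.full(n, 0.3),  # phi_22 AR outcome
                inter + sd * rng.standard_normal(n),  # phi_2.12
            ]
        )
        return StandardizedDraws(
            term_labels=["phi_11", "phi_21", "phi_22", "phi_2.12"],
            coefs=coefs,
            unstandardized=coefs.copy(),
            state_sd=np.ones((n, 2)),
            innovation_var=np.ones((n, 2)),
        )

    def test_reported_slope_arithmetic(self, spec_a):
        # standardized CR 0.074 with interaction -0.063: slope 0.011 at
        # moderator +1 SD and 0.137 at -1 SD
        std = self._std(0.074, -0.063, n=10)
        surf = m.simple_slopes(std, spec_a, moderator_values=(-1, 0, 1))
        assert surf.slope_mean[0] == pytest.approx(0.137)
        assert surf.slope_mean[1] == pytest.approx(0.074)  # equals CR at 0
        assert surf.slope_mean[2] == pytest.approx(0.011)

    def test_zero_interaction_gives_parallel_slopes(self, spec_a):
        std = self._std(0.2, 0.0, n=10)
        surf = m.simple_slopes(std, spec_a)
        assert np.allclose(surf.slope_mean, 0.2)

    def test_slope_at_zero_moderator_equals_cr_per_draw(self, spec_a):
        std = self._std(0.1, -0.05, n=200, sd=0.03)
        surf = m.simple_slopes(std, spec_a, moderator_values=(0.0,))
        assert surf.slope_mean[0] == pytest.approx(std.coefs[:, 1].mean(), abs=1e-12)

    def test_band_collapses_for_degenerate_posterior(self, spec_a):
        tight = m.simple_slopes(self._std(0.1, -0.05, sd=0.0), spec_a)
        wide = m.simple_slopes(self._std(0.1, -0.05, sd=0.05), spec_a)
        assert np.allclose(tight.lo, tight.hi, atol=1e-12)
        assert (wide.hi - wide.lo).max() > 0.1

    def test_surface_frame_and_band_contains_mean(self, spec_a):
        std = self._std(0.1, -0.05, sd=0.02)
        surf = m.simple_slopes(std, spec_a, ar_outcome_level=1.0)
        assert np.all(surf.lo <= surf.mean + 1e-12)
        assert np.all(surf.mean <= surf.hi + 1e-12)
        df = surf.to_frame()
        assert set(df.columns) == {"moderator", "predictor", "mean", "lo", "hi"}


class TestRegionOfSignificance:
    def _std(self, cr_mean, cr_sd, inter, n=4000, seed=2):
        rng = np.random.default_rng(seed)
        coefs = np.column_stack(
            [
                np.full(n, 0.35),
                cr_mean + cr_sd * rng.standard_normal(n),
                np.full(n, 0.3),
                np.full(n, inter),
            ]
        )
        return StandardizedDraws(
            term_labels=["phi_11", "phi_21", "phi_22", "phi_2.12"],
            coefs=coefs,
            unstandardized=coefs.copy(),
            state_sd=np.ones((n, 2)),
            innovation_var=np.ones((n, 2)),
        )

    def test_always_significant_slope_has_empty_nonsignificant_region(self, spec_a):
        std = self._std(0.5, 0.01, -0.01)
        out = m.region_of_significance(std, spec_a, np.linspace(-2, 2, 101))
        assert out["significant"].all()
        assert out["boundaries"] == []

    def test_monotone_case_single_boundary_matches_quantile_crossing(self, spec_a):
        # slope(m) = cr - 0.05 m with cr ~ N(0.1, 0.01^2): the 2.5% bound
        # crosses zero near m = (0.1 - 1.96 * 0.01) / 0.05 ~ 1.6
        # grid stops before the far point where the upper bound also
        # crosses zero (slope significantly negative again)
        std = self._std(0.1, 0.01, -0.05)
        out = m.region_of_significance(std, spec_a, np.linspace(-2.2, 2.2, 441))
        assert len(out["boundaries"]) == 1
        lo_q = np.quantile(std.coefs[:, 1], 0.025)
        assert out["boundaries"][0] == pytest.approx(lo_q / 0.05, abs=0.02)
        sig = out["significant"]
        assert sig[0] and not sig[-1]
        # contiguous: exactly one flip
        assert int(np.sum(sig[1:] != sig[:-1])) == 1
        # quantile band contains the mean slope pointwise
        assert np.all(out["slope_lo"] <= out["slope_mean"])
        assert np.all(out["slope_mean"] <= out["slope_hi"])


class TestVarianceExplained:
    def test_pure_ar_closed_form(self):
        spec = ModelSpec(
            constructs=[ConstructDef("x")], terms=[LagTerm(0, 0, "AR")], name="ar1"
        )
        vals = {
            "phi_11": 0.5, "sigma_zeta_1": 1.0,
            "gamma_mu_1": 5.0, "tau_mu_1": 0.8,
        }
        draws = make_draws(spec, vals, n=4)
        r2, summ = m.variance_explained(draws, spec, outcome=0)
        assert np.allclose(r2, 0.25, atol=1e-10)

    def test_no_dynamics_zero_r2(self):
        spec = ModelSpec(
            constructs=[ConstructDef("x")], terms=[LagTerm(0, 0, "AR")], name="ar1"
        )
        vals = {"phi_11": 0.0, "sigma_zeta_1": 1.0, "gamma_mu_1": 5.0, "tau_mu_1": 0.8}
        draws = make_draws(spec, vals, n=4)
        r2, _ = m.variance_explained(draws, spec, outcome=0)
        assert np.allclose(r2, 0.0, atol=1e-12)

    def test_interaction_model_r2_in_unit_interval_and_near_simulation(self, spec_a):
        draws = make_draws(spec_a, MODEL_A_VALUES, n=4)
        r2, summ = m.variance_explained(draws, spec_a, outcome=1, n_steps=200_000, seed=3)
        assert np.all((r2 >= 0) & (r2 <= 1))
        # cross-check against an independent simulation's empirical variance
        phi = np.array([[0.35, 0.15, 0.3, 0.1]])
        chol = np.linalg.cholesky(np.diag([0.78**2, 0.78**2]))[None]
        eta = dynamics.simulate_series(
            spec_a, phi, chol, 150_000, 500, np.random.default_rng(123)
        )[0]
        expect = 1.0 - 0.78**2 / eta[:, 1].var()
        assert summ["mean"] == pytest.approx(expect, abs=0.02)


class TestItemReliability:
    def _draws(self, sigma_eps):
        spec = m.build_model("A", factor=True)
        vals = dict(MODEL_A_VALUES)
        for q in (1, 2):
            for p in (2, 3):
                vals[f"lambda_w_{q}_{p}"] = 1.0
                vals[f"lambda_b_{q}_{p}"] = 1.0
                vals[f"alpha_{q}_{p}"] = 0.0
            for p in (1, 2, 3):
                vals[f"sigma_eps_w_{q}_{p}"] = sigma_eps
        return spec, make_draws(spec, vals, n=4)

    def test_zero_error_gives_unit_reliability(self):
        spec, draws = self._draws(1e-8)
        tab = m.item_reliability(draws, spec, n_steps=20_000)
        assert np.allclose(tab["reliability"], 1.0, atol=1e-6)

    def test_equal_split_gives_half(self, spec_a):
        spec, draws = self._draws(1.0)
        tab = m.item_reliability(draws, spec, n_steps=300_000, seed=4)
        phi = np.array([[0.35, 0.15, 0.3, 0.1]])
        chol = np.linalg.cholesky(np.diag([0.78**2, 0.78**2]))[None]
        mom = dynamics.simulate_moments(
            spec_a, phi, chol, 300_000, 500, np.random.default_rng(9)
        )
        v = mom["state_var"][0]
        expect = np.repeat(v / (v + 1.0), 3)
        assert np.allclose(tab["reliability"], expect, atol=0.01)

    def test_single_indicator_model_rejected(self, spec_a):
        draws = make_draws(spec_a, MODEL_A_VALUES, n=4)
        with pytest.raises(ConfigurationError):
            m.item_reliability(draws, spec_a)


class TestRandomEffectSummaries:
    def test_fixed_effects_model_rejected(self, spec_a):
        draws = make_draws(spec_a, MODEL_A_VALUES, n=4)
        with pytest.raises(ConfigurationError):
            m.random_effect_summaries(draws, spec_a)

    def test_constructed_person_draws_quantiles(self):
        spec = m.build_model("ex2")
        pidx = parameter_index(spec)
        eff = pidx.person_effects
        S, N, K = 30, 40, len(eff)
        rng = np.random.default_rng(3)
        # person effects: traits near 5, phi spread across persons
        E = np.zeros((2, S // 2, N, K))
        E[..., :2] = 5.0
        person_phi = 0.3 + 0.1 * rng.standard_normal(N)
        E[..., eff.index("phi_22")] = person_phi
        E[..., eff.index("phi_11")] = 0.3
        E[..., eff.index("phi_12")] = 0.1
        E[..., eff.index("phi_21")] = 0.2
        E[..., eff.index("phi_2.12")] = 0.05
        E[..., eff.index("ln_sigma2_delta_1")] = -0.5
        E[..., eff.index("ln_sigma2_delta_2")] = -0.5
        vals = {nm: 0.0 for nm in pidx.names}
        vals.update(
            {
                "phi_11": 0.3, "phi_12": 0.1, "phi_21": 0.2, "phi_22": 0.3,
                "phi_2.12": 0.05,
                "gamma_ln_sigma2_delta_1": -0.5, "gamma_ln_sigma2_delta_2": -0.5,
                "gamma_mu_1": 5.0, "gamma_mu_2": 5.0,
            }
        )
        for nm in pidx.names:
            if nm.startswith("tau_"):
                vals[nm] = 0.1
        draws = make_draws(spec, vals, n=S)
        draws.person_draws = E
        draws.person_effect_names = eff
        out = m.random_effect_summaries(
            draws, spec, n_steps=20_000, max_draws=10
        )
        tab = out["person_table"]
        assert len(tab) == N
        lo, hi = out["central95"]["phi_22"]
        assert lo < np.median(tab["phi_22"]) < hi
        # AR standardization leaves person AR effects unchanged, so the
        # person spread mirrors the constructed spread
        assert tab["phi_22"].std() == pytest.approx(person_phi.std(), rel=0.05)
        assert "correlations" in out


class TestPlot:
    def test_interaction_plot_draws_mean_and_band_lines(self, spec_a):
        import matplotlib

        matplotlib.use("Agg")
        from mlmvar.postprocess import plot_interaction

        n = 20
        coefs = np.column_stack(
            [np.full(n, 0.3), np.full(n, 0.1), np.full(n, 0.3), np.full(n, -0.05)]
        )
        std = StandardizedDraws(
            ["phi_11", "phi_21", "phi_22", "phi_2.12"],
            coefs, coefs.copy(), np.ones((n, 2)), np.ones((n, 2)),
        )
        surf = m.simple_slopes(std, spec_a)
        ax = plot_interaction(surf)
        # one mean line + two band lines per moderator value
        assert len(ax.lines) == 3 * len(surf.moderator_values)
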