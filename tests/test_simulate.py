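"""Data generation: between-level draws, stationarity screen, recursion,
measurement layer, and the closed-form/brute-force oracles."""

import numpy as np
import pytest

import mlmvar as m
from mlmvar import dynamics
from mlmvar.errors import ConfigurationError
from mlmvar.modelspec import ConstructDef, LagTerm, ModelSpec


def ar1_spec(label="x"):
    return ModelSpec(constructs=[ConstructDef(label)], terms=[LagTerm(0, 0, "AR")], name="ar1")


class TestPersonParams:
    def test_zero_variances_reproduce_fixed_effects(self, spec_a, rng):
        cfg = m.default_gen_config(spec_a, trait_sds=[0.0, 0.0])
        pps = [m.draw_person_params(cfg, spec_a, rng) for _ in range(5)]
        for pp in pps:
            assert np.allclose(pp.mu, [5.0, 5.0])
            assert np.allclose(
                pp.phi, [0.35, 0.15, 0.3, 0.1]
            )

    def test_log_innovation_closed_form(self, rng):
        # log-variance -0.5 with no spread -> variance exp(-0.5) ~ 0.6065
        spec = m.build_model("A")
        cfg = m.default_gen_config(spec)
        pp = m.draw_person_params(cfg, spec, rng)
        assert np.allclose(np.diag(pp.innovation_cov), np.exp(-0.5), atol=1e-12)

    def test_rejection_truncates_random_ar_spread(self):
        # wide random AR spread: accepted draws must stay inside the
        # stationarity screen, so their spread cannot exceed tau
        spec = m.build_model("A", random_effects=True)
        cfg = m.default_gen_config(
            spec, n_times=20, burn_in=50, phi_sd=0.45,
            fixed_effects={"phi_11": 0.6, "phi_21": 0.15, "phi_22": 0.3, "phi_2.12": 0.1},
        )
        rng = np.random.default_rng(5)
        draws = [m.draw_person_params(cfg, spec, rng) for _ in range(300)]
        ar = np.array([pp.phi[0] for pp in draws])
        assert np.abs(ar).max() < 1.0
        assert ar.std() <= 0.45
        assert any(pp.rejections > 0 for pp in draws)

    def test_impossible_generating_values_error(self, rng):
        spec = m.build_model("A")
        cfg = m.default_gen_config(
            spec,
            fixed_effects={"phi_11": 1.5, "phi_21": 0.1, "phi_22": 0.3, "phi_2.12": 0.1},
            max_rejections=20,
        )
        with pytest.raises(ConfigurationError, match="stationarity"):
            m.draw_person_params(cfg, spec, rng)


class TestStationarityScreen:
    def _pp(self, spec, phi, var=0.6):
        Q = spec.n_constructs
        return m.PersonParams(
            phi=np.asarray(phi, dtype=float),
            innovation_cov=np.eye(Q) * var,
            mu=np.full(Q, 5.0),
        )

    def test_generating_range_passes(self, spec_a):
        cfg = m.default_gen_config(spec_a)
        ok, diag = m.check_stationarity(
            self._pp(spec_a, [0.3, 0.1, 0.35, 0.1]), spec_a, cfg
        )
        assert ok and diag["spectral_radius"] < 1

    def test_explosive_ar_fails(self, spec_a):
        cfg = m.default_gen_config(spec_a)
        ok, diag = m.check_stationarity(
            self._pp(spec_a, [1.2, 0.1, 0.3, 0.1]), spec_a, cfg
        )
        assert not ok and not diag["ar_in_range"]

    def test_linearly_stable_but_interaction_divergent_fails(self, spec_a):
        # spectral radius of the linearized system is < 1, yet the strong
        # product term makes trajectories explode -> screening catches it
        cfg = m.default_gen_config(spec_a, n_times=200, burn_in=200)
        pp = self._pp(spec_a, [0.95, 0.0, 0.5, 1.5])
        rad = dynamics.companion_spectral_radius(spec_a, pp.phi[None])[0]
        assert rad < 1
        ok, diag = m.check_stationarity(pp, spec_a, cfg, np.random.default_rng(0))
        assert not ok and not diag["screen_finite"]


class TestRecursion:
    def test_zero_innovations_fixed_point(self, spec_a):
        pp = m.PersonParams(
            phi=np.array([0.35, 0.15, 0.3, 0.1]),
            innovation_cov=np.zeros((2, 2)),
            mu=np.zeros(2),
        )
        eta = dynamics.simulate_series(
            spec_a, pp.phi[None], np.zeros((1, 2, 2)), 20, 10, np.random.default_rng(0)
        )
        assert np.all(eta == 0.0)

    def test_pure_ar_stationary_variance(self):
        spec = ar1_spec()
        eta = dynamics.simulate_series(
            spec,
            np.array([[0.3]]),
            np.ones((1, 1, 1)),
            100_000,
            500,
            np.random.default_rng(11),
        )
        assert np.var(eta) == pytest.approx(1.0 / (1.0 - 0.09), rel=0.02)

    def test_interaction_recursion_matches_bruteforce_loop(self, spec_a):
        # element-by-element reference recursion on the same innovations
        phi = np.array([0.35, 0.15, 0.3, 0.12])
        chol = np.linalg.cholesky(np.array([[0.6, 0.1], [0.1, 0.5]]))
        T, burn = 40, 10
        rng = np.random.default_rng(99)
        eta = dynamics.simulate_series(spec_a, phi[None], chol[None], T, burn, rng)[0]
        noise = np.random.default_rng(99).standard_normal((burn + T, 1, 2))
        e1 = e2 = 0.0
        ref = []
        for t in range(burn + T):
            z = chol @ noise[t, 0]
            n1 = phi[0] * e1 + z[0]
            n2 = phi[1] * e1 + phi[2] * e2 + phi[3] * (e1 * e2) + z[1]
            e1, e2 = n1, n2
            if t >= burn:
                ref.append([e1, e2])
        assert np.allclose(eta, np.array(ref), atol=1e-12)

    def test_closed_form_var1_covariance_oracle(self):
        # interaction-free two-construct model: empirical moments match
        # vec(Sigma) = (I - Phi kron Phi)^-1 vec(Sigma_zeta)
        spec = ModelSpec(
            constructs=[ConstructDef("a"), ConstructDef("b")],
            terms=[LagTerm(0, 0, "AR"), LagTerm(1, 0, "CR"), LagTerm(1, 1, "AR")],
        )
        phi = np.array([[0.4, 0.2, 0.3]])
        cov = np.array([[0.7, 0.15], [0.15, 0.5]])
        S_closed = dynamics.stationary_cov_linear(spec, phi, cov[None])[0]
        eta = dynamics.simulate_series(
            spec, phi, np.linalg.cholesky(cov)[None], 200_000, 500,
            np.random.default_rng(3),
        )[0]
        S_emp = np.cov(eta.T)
        assert np.allclose(S_emp, S_closed, rtol=0.03, atol=0.01)


class TestDatasets:
    def test_row_count_is_n_times_t(self, spec_a):
        cfg = m.default_gen_config(spec_a, n_persons=25, n_times=25)
        panel = m.simulate_dataset(cfg, spec_a, 1)
        assert len(panel.df) == 625

    def test_same_seed_identical(self, spec_a):
        cfg = m.default_gen_config(spec_a, n_persons=5, n_times=15)
        a = m.simulate_dataset(cfg, spec_a, 77)
        b = m.simulate_dataset(cfg, spec_a, 77)
        assert a.df.equals(b.df)
        assert np.array_equal(a.latent_truth["eta_w"], b.latent_truth["eta_w"])

    def test_errorfree_single_indicator_recovers_latent(self, spec_a):
        cfg = m.default_gen_config(spec_a, n_persons=6, n_times=30)
        panel = m.simulate_dataset(cfg, spec_a, 2)
        arr = panel.to_arrays(spec_a)
        mu = panel.latent_truth["mu"]
        eta = arr["y"] - mu[:, None, :]
        assert np.allclose(eta, panel.latent_truth["eta_w"], atol=1e-10)

    def test_icc_and_reliability_match_study_conditions(self):
        spec = m.build_model("A", factor=True)
        cfg = m.default_gen_config(spec, n_persons=300, n_times=120)
        panel = m.simulate_dataset(cfg, spec, 8)
        arr = panel.to_arrays(spec)
        y = arr["y"]  # (N, T, 6)
        pm = y.mean(axis=1)
        wvar = y.var(axis=1).mean(axis=0)
        bvar = pm.var(axis=0, ddof=1) - wvar / y.shape[1]
        icc = bvar / (bvar + wvar)
        assert np.all(icc > 0.35) and np.all(icc < 0.55)
        assert icc.mean() == pytest.approx(0.45, abs=0.06)
        # within-level reliability: 1 - error variance / total within variance
        rel = 1.0 - 0.3 / wvar
        assert rel.mean() == pytest.approx(0.72, abs=0.04)

    def test_grid_template_and_missingness(self, spec_a):
        grid = m.GridTemplate(beeps_per_day=6, days=5)
        cfg = m.default_gen_config(
            spec_a, n_persons=4, n_times=30, grid=grid, missing_rate=0.15
        )
        panel = m.simulate_dataset(cfg, spec_a, 5)
        per_person = panel.df.groupby("person")["lag_valid"].apply(lambda s: (~s).sum())
        assert (per_person == 5).all()
        assert panel.df[panel.all_y_columns].isna().any().any()


class TestCommonFactorCovariance:
    def test_unit_components(self):
        cov = dynamics.common_factor_cov(np.zeros((1, 2)), np.zeros(1))[0]
        assert np.allclose(cov, [[2.0, 1.0], [1.0, 2.0]])
        assert cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]) == pytest.approx(0.5)

    def test_generating_values(self):
        cov = dynamics.common_factor_cov(
            np.full((1, 2), -0.7), np.array([-1.3])
        )[0]
        assert cov[0, 1] == pytest.approx(np.exp(-1.3))
        assert cov[0, 0] == pytest.approx(np.exp(-0.7) + np.exp(-1.3))

    def test_positive_definite_over_random_grid(self, rng):
        for _ in range(50):
            ln_d = rng.normal(0, 2, size=(1, 3))
            ln_f = rng.normal(0, 2, size=1)
            sign = rng.choice([-1, 1])
            cov = dynamics.common_factor_cov(ln_d, ln_f, sign)[0]
            assert np.linalg.eigvalsh(cov).min() > 0
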