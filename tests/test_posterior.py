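"""Posterior density: oracle equality, reparameterizations, fit contract."""

import numpy as np
import pytest

import mlmvar as m
from mlmvar.errors import EstimationError
from mlmvar.modelspec import ConstructDef, LagTerm, ModelSpec

from _oracles import naive_log_density


def _pack_and_compare(spec, panel, gc, Z, latent=None, miss=None, initial="stationary"):
    priors = m.PriorConfig()
    lp = m.LogPosterior(spec, priors, panel, initial_state=initial)
    theta = lp.pack(gc, Z=Z, latent=latent, miss=miss)
    g, p = lp.evaluate(theta)
    ours = g + p.sum()
    ref = naive_log_density(
        spec, priors, panel, gc, Z, latent=latent, miss=miss, initial_state=initial
    )
    assert ours == pytest.approx(ref, abs=1e-10, rel=1e-12)
    return ours


class TestLogDensityOracle:
    def test_single_indicator_model_a_small_instance(self, spec_a):
        cfg = m.default_gen_config(spec_a, n_persons=2, n_times=4, burn_in=20)
        panel = m.simulate_dataset(cfg, spec_a, 31)
        gc = {
            "phi_11": 0.3, "phi_21": 0.12, "phi_22": 0.25, "phi_2.12": 0.07,
            "sigma_zeta_1": 0.8, "sigma_zeta_2": 0.7,
            "gamma_mu_1": 5.1, "gamma_mu_2": 4.9,
            "tau_mu_1": 0.7, "tau_mu_2": 0.9,
        }
        Z = np.array([[0.3, -0.2], [-1.1, 0.6]])
        _pack_and_compare(spec_a, panel, gc, Z)

    def test_missing_cells_become_free_states(self, spec_a):
        cfg = m.default_gen_config(spec_a, n_persons=3, n_times=5, burn_in=20)
        panel = m.simulate_dataset(cfg, spec_a, 32)
        panel.df.loc[2, "y_eta1_1"] = np.nan
        panel.df.loc[8, "y_eta2_1"] = np.nan
        panel = m.PanelData(panel.df, panel.y_columns)
        gc = {
            "phi_11": 0.35, "phi_21": 0.1, "phi_22": 0.3, "phi_2.12": 0.05,
            "sigma_zeta_1": 0.75, "sigma_zeta_2": 0.75,
            "gamma_mu_1": 5.0, "gamma_mu_2": 5.0,
            "tau_mu_1": 0.8, "tau_mu_2": 0.8,
        }
        Z = np.array([[0.1, 0.2], [-0.4, 0.9], [1.2, -0.7]])
        miss = {0: np.array([0.33]), 1: np.array([-0.41])}
        _pack_and_compare(spec_a, panel, gc, Z, miss=miss)

    def test_factor_model_with_latent_states(self):
        spec = m.build_model("A", factor=True, inncov=False)
        cfg = m.default_gen_config(spec, n_persons=2, n_times=3, burn_in=20)
        panel = m.simulate_dataset(cfg, spec, 33)
        gc = {
            "phi_11": 0.3, "phi_21": 0.1, "phi_22": 0.28, "phi_2.12": 0.06,
            "sigma_zeta_1": 0.8, "sigma_zeta_2": 0.72,
            "gamma_mu_1": 5.0, "gamma_mu_2": 4.8,
            "tau_mu_1": 0.9, "tau_mu_2": 1.0,
        }
        for q in (1, 2):
            for p in (2, 3):
                gc[f"lambda_w_{q}_{p}"] = 0.9 + 0.05 * p
                gc[f"lambda_b_{q}_{p}"] = 1.1 - 0.05 * p
                gc[f"alpha_{q}_{p}"] = 0.1 * p
            for p in (1, 2, 3):
                gc[f"sigma_eps_w_{q}_{p}"] = 0.5 + 0.05 * p
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(2, 2))
        latent = {0: rng.normal(size=(2, 3)), 1: rng.normal(size=(2, 3))}
        _pack_and_compare(spec, panel, gc, Z, latent=latent)

    def test_random_effects_lag0_variant(self):
        spec = m.build_model("ex2")
        cfg = m.default_gen_config(spec, n_persons=2, n_times=4, burn_in=20)
        panel = m.simulate_dataset(cfg, spec, 34)
        gc = {
            "phi_11": 0.3, "phi_12": 0.1, "phi_21": 0.2, "phi_22": 0.25,
            "phi_2.12": 0.08,
            "gamma_ln_sigma2_delta_1": -0.6, "gamma_ln_sigma2_delta_2": -0.5,
            "gamma_mu_1": 5.0, "gamma_mu_2": 5.0,
            "tau_mu_1": 0.8, "tau_mu_2": 0.7,
            "tau_phi_11": 0.1, "tau_phi_12": 0.1, "tau_phi_21": 0.12,
            "tau_phi_22": 0.1, "tau_phi_2.12": 0.08,
            "tau_ln_sigma2_delta_1": 0.4, "tau_ln_sigma2_delta_2": 0.4,
        }
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(2, 9)) * 0.5
        _pack_and_compare(spec, panel, gc, Z)

    def test_conditional_mode_drops_initial_state_terms(self, spec_a):
        cfg = m.default_gen_config(spec_a, n_persons=2, n_times=4, burn_in=20)
        panel = m.simulate_dataset(cfg, spec_a, 35)
        gc = {
            "phi_11": 0.3, "phi_21": 0.12, "phi_22": 0.25, "phi_2.12": 0.07,
            "sigma_zeta_1": 0.8, "sigma_zeta_2": 0.7,
            "gamma_mu_1": 5.1, "gamma_mu_2": 4.9,
            "tau_mu_1": 0.7, "tau_mu_2": 0.9,
        }
        Z = np.zeros((2, 2))
        _pack_and_compare(spec_a, panel, gc, Z, initial="conditional")


class TestDynamicTermExclusion:
    def test_segment_starts_contribute_no_lagged_terms(self, spec_a):
        # with every lag invalid and conditional initial states, the
        # density cannot depend on any dynamic coefficient
        cfg = m.default_gen_config(spec_a, n_persons=3, n_times=4, burn_in=20)
        panel = m.simulate_dataset(cfg, spec_a, 36)
        panel.df["lag_valid"] = False
        panel = m.PanelData(panel.df, panel.y_columns)
        lp = m.LogPosterior(spec_a, m.PriorConfig(), panel, initial_state="conditional")
        gc = {
            "phi_11": 0.3, "phi_21": 0.12, "phi_22": 0.25, "phi_2.12": 0.07,
            "sigma_zeta_1": 0.8, "sigma_zeta_2": 0.7,
            "gamma_mu_1": 5.0, "gamma_mu_2": 5.0, "tau_mu_1": 0.8, "tau_mu_2": 0.8,
        }
        t1 = lp.pack(gc, Z=np.zeros((3, 2)))
        gc2 = dict(gc, **{"phi_11": -0.2, "phi_2.12": 0.9})
        t2 = lp.pack(gc2, Z=np.zeros((3, 2)))
        g1, p1 = lp.evaluate(t1)
        g2, p2 = lp.evaluate(t2)
        lik1 = g1 + p1.sum() - lp.global_prior(t1)
        lik2 = g2 + p2.sum() - lp.global_prior(t2)
        assert lik1 == pytest.approx(lik2, abs=1e-12)

    def test_overnight_boundary_skips_lag_across_days(self, spec_a):
        # moving an observation across a day boundary changes the dynamic
        # likelihood only through the removed lag term
        grid = m.GridTemplate(beeps_per_day=3, days=2)
        cfg = m.default_gen_config(spec_a, n_persons=2, n_times=6, grid=grid, burn_in=20)
        panel = m.simulate_dataset(cfg, spec_a, 37)
        arr = panel.to_arrays(spec_a)
        # day starts at occasions 0 and 3
        assert (~arr["lag_valid"][:, [0, 3]]).all()
        assert arr["lag_valid"][:, [1, 2, 4, 5]].all()


class TestInnovationReparam:
    def test_unit_components_covariance(self):
        cov = m.innovation_covariance_reparam(np.zeros((1, 2)), 0.0)[0]
        assert np.allclose(cov, [[2, 1], [1, 2]])

    def test_negative_sign_flips_covariance(self):
        cov = m.innovation_covariance_reparam(np.zeros((1, 2)), 0.0, sign=-1)[0]
        assert cov[0, 1] == pytest.approx(-1.0)
        assert np.linalg.eigvalsh(cov).min() > 0


class TestParameterizationConsistency:
    def test_equivalent_effect_points_share_likelihood(self, spec_a):
        # two (gamma, tau, z) combinations implying identical person
        # effects must give identical likelihood terms (non-centered map
        # is a pure reparameterization)
        cfg = m.default_gen_config(spec_a, n_persons=3, n_times=6, burn_in=20)
        panel = m.simulate_dataset(cfg, spec_a, 40)
        lp = m.LogPosterior(spec_a, m.PriorConfig(), panel)
        base = {
            "phi_11": 0.3, "phi_21": 0.12, "phi_22": 0.25, "phi_2.12": 0.07,
            "sigma_zeta_1": 0.8, "sigma_zeta_2": 0.7,
        }
        gc1 = dict(base, gamma_mu_1=5.0, gamma_mu_2=5.0, tau_mu_1=0.8, tau_mu_2=0.8)
        Z1 = np.array([[0.5, -0.5], [0.0, 1.0], [-1.0, 0.25]])
        gc2 = dict(base, gamma_mu_1=4.8, gamma_mu_2=5.4, tau_mu_1=0.4, tau_mu_2=1.6)
        Z2 = np.empty_like(Z1)
        Z2[:, 0] = (5.0 + 0.8 * Z1[:, 0] - 4.8) / 0.4
        Z2[:, 1] = (5.0 + 0.8 * Z1[:, 1] - 5.4) / 1.6
        t1 = lp.pack(gc1, Z=Z1)
        t2 = lp.pack(gc2, Z=Z2)
        E1 = lp.person_effects(t1)[1]
        E2 = lp.person_effects(t2)[1]
        assert np.allclose(E1, E2, atol=1e-12)
        z1sq = 0.5 * (Z1**2).sum()
        z2sq = 0.5 * (Z2**2).sum()
        g1, p1 = lp.evaluate(t1)
        g2, p2 = lp.evaluate(t2)
        lik1 = g1 + p1.sum() - lp.global_prior(t1) + z1sq
        lik2 = g2 + p2.sum() - lp.global_prior(t2) + z2sq
        assert lik1 == pytest.approx(lik2, abs=1e-9)


class TestFastPathEquivalence:
    @pytest.mark.parametrize("initial", ["stationary", "conditional"])
    @pytest.mark.parametrize("inncov", [False, True])
    def test_compiled_and_vectorized_likelihood_agree(self, initial, inncov):
        spec = m.build_model("A", inncov=inncov)
        cfg = m.default_gen_config(spec, n_persons=12, n_times=18, burn_in=50)
        panel = m.simulate_dataset(cfg, spec, 61)
        lp = m.LogPosterior(spec, m.PriorConfig(), panel, initial_state=initial)
        assert lp.use_fast
        rng = np.random.default_rng(5)
        for _ in range(10):
            theta = lp.initial_theta(rng, jitter=1.5)
            theta += 0.05 * rng.standard_normal(lp.dim)
            g1, p1 = lp.evaluate(theta)
            lp.use_fast = False
            g2, p2 = lp.evaluate(theta)
            lp.use_fast = True
            assert g1 == pytest.approx(g2, abs=1e-10)
            assert np.allclose(p1, p2, atol=1e-9)

    def test_general_configurations_use_vectorized_route(self):
        for kw in ({"factor": True}, {"random_effects": True}):
            spec = m.build_model("A", **kw)
            cfg = m.default_gen_config(spec, n_persons=3, n_times=6, burn_in=20)
            panel = m.simulate_dataset(cfg, spec, 62)
            lp = m.LogPosterior(spec, m.PriorConfig(), panel)
            assert not lp.use_fast


class TestPriorPredictive:
    def test_generative_push_forward_is_finite(self, rng):
        # draw moderate parameter sets and push them through the
        # generative model: data stay finite
        spec = m.build_model("A", random_effects=True, inncov=True)
        cfg = m.default_gen_config(spec, n_persons=5, n_times=15, burn_in=50)
        for seed in range(3):
            panel = m.simulate_dataset(cfg, spec, seed)
            assert np.isfinite(panel.df[panel.all_y_columns].to_numpy()).all()

    def test_nonfinite_parameters_give_minus_inf(self, spec_a, small_panel):
        lp = m.LogPosterior(spec_a, m.PriorConfig(), small_panel)
        theta = lp.initial_theta(np.random.default_rng(0))
        theta[0] = np.nan
        g, p = lp.evaluate(theta)
        assert not np.isfinite(g + p.sum())


class TestFit:
    def test_recovery_smoke(self):
        spec = m.build_model("A")
        cfg = m.default_gen_config(spec, n_persons=40, n_times=40)
        panel = m.simulate_dataset(cfg, spec, 50)
        draws = m.fit(spec, None, panel, chains=2, iterations=1500, seed=4)
        truth = panel.latent_truth["truth_vector"]
        means = dict(zip(draws.names, draws.mean()))
        for nm in ("phi_11", "phi_21", "phi_22", "phi_2.12"):
            assert means[nm] == pytest.approx(truth[nm], abs=0.12)
        assert int(draws.n_divergent.sum()) == 0

    def test_degenerate_data_raises(self, spec_a):
        cfg = m.default_gen_config(spec_a, n_persons=3, n_times=6, burn_in=20)
        panel = m.simulate_dataset(cfg, spec_a, 51)
        for c in panel.all_y_columns:
            panel.df[c] = 5.0
        panel = m.PanelData(panel.df, panel.y_columns)
        with pytest.raises(EstimationError, match="degenerate"):
            m.fit(spec_a, None, panel, chains=2, iterations=200, seed=0)

    def test_single_chain_rejected(self, spec_a, small_panel):
        with pytest.raises(EstimationError):
            m.fit(spec_a, None, small_panel, chains=1, iterations=200, seed=0)

    def test_draws_table_round_trip(self, tmp_path, spec_a, small_panel):
        draws = m.fit(spec_a, None, small_panel, chains=2, iterations=300, seed=1)
        path = tmp_path / "draws.csv"
        draws.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns[2:]) == draws.names
        assert len(back) == draws.flat().shape[0]
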