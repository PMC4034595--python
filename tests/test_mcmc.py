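"""Chain protocol, sampler determinism, diagnostics, and the grid oracle."""

import numpy as np
import pytest

import predmort as pm
from predmort import mcmc

from conftest import make_table


def fake_samples(arrays, model="predator_effect"):
    """Wrap raw per-chain arrays as PosteriorSamples for diagnostic tests."""
    draws = {"x": np.asarray(arrays, dtype=float)}
    cfg = pm.ChainConfig(n_chains=len(arrays), n_steps=len(arrays[0]),
                         thin=1, burn_in=0, seed=0)
    return mcmc.PosteriorSamples(draws=draws, config=cfg, model=model)


class TestChainConfig:
    def test_default_protocol_retains_ten_thousand_per_chain(self):
        cfg = pm.ChainConfig()
        assert cfg.n_chains == 3
        assert cfg.n_steps == 10 ** 6
        assert cfg.thin == 100
        assert cfg.burn_in == 2_000
        assert cfg.n_retained_per_chain == 10 ** 4
        assert cfg.n_chains * cfg.n_retained_per_chain == 3 * 10 ** 4

    @pytest.mark.parametrize("kw", [
        {"n_steps": 50, "thin": 100},    # no retained draws
        {"n_steps": 150, "thin": 100},   # thin must divide n_steps
        {"n_chains": 0},
        {"burn_in": -1},
        {"thin": 0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(mcmc.ChainConfigError):
            pm.ChainConfig(**kw)


class TestRunChains:
    def test_same_seed_identical_draws(self, predation_table):
        table, _ = predation_table
        cfg = pm.ChainConfig(n_chains=2, n_steps=1_000, thin=10, burn_in=100, seed=9)
        s1 = pm.run_chains(table, "predator_effect", config=cfg)
        s2 = pm.run_chains(table, "predator_effect", config=cfg)
        assert s1.parameter_names == s2.parameter_names
        for name in s1.parameter_names:
            np.testing.assert_array_equal(s1.chains(name), s2.chains(name))

    def test_different_seed_differs(self, predation_table):
        table, _ = predation_table
        cfg = pm.ChainConfig(n_chains=1, n_steps=1_000, thin=10, burn_in=100, seed=9)
        cfg2 = pm.ChainConfig(n_chains=1, n_steps=1_000, thin=10, burn_in=100, seed=10)
        s1 = pm.run_chains(table, "predator_effect", config=cfg)
        s2 = pm.run_chains(table, "predator_effect", config=cfg2)
        assert not np.array_equal(s1.chains("intercept"), s2.chains("intercept"))

    def test_parameter_set_matches_model(self, trait_samples, predation_table):
        table, _ = predation_table
        groups = table.group_labels()
        expected = (["intercept", "log_mass", "ambush", "suctorial"]
                    + [f"predator[{g}]" for g in groups]
                    + ["sigma_predator", "sigma_obs"])
        assert trait_samples.parameter_names == expected

    def test_retained_count_honoured(self, trait_samples, quick_config):
        assert trait_samples.n_per_chain == quick_config.n_retained_per_chain
        assert trait_samples.n_chains == quick_config.n_chains

    def test_degenerate_all_dead_data_is_not_an_error(self):
        table = make_table([("v1", "g", 1, 10, 10), ("v2", "g", 1, 10, 10)])
        cfg = pm.ChainConfig(n_chains=2, n_steps=500, thin=10, burn_in=50, seed=1)
        s = pm.run_chains(table, "predator_effect", config=cfg)
        # prior keeps the intercept finite despite separation
        assert np.isfinite(s.pooled("intercept")).all()

    def test_round_trip_csv(self, tmp_path, trait_samples):
        path = tmp_path / "samples.csv"
        trait_samples.to_csv(path)
        back = mcmc.PosteriorSamples.from_csv(path)
        assert back.model == trait_samples.model
        assert back.parameter_names == trait_samples.parameter_names
        for nm in back.parameter_names:
            np.testing.assert_allclose(back.chains(nm), trait_samples.chains(nm))


class TestGelmanRubin:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        s = fake_samples(rng.standard_normal((3, 10_000)))
        assert mcmc.gelman_rubin_psrf(s, "x") < 1.01

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((3, 500))
        chains[2] += 10.0
        s = fake_samples(chains)
        assert mcmc.gelman_rubin_psrf(s, "x") > 1.1

    def test_identical_constant_chains_convention(self):
        s = fake_samples(np.full((3, 200), 2.5))
        assert mcmc.gelman_rubin_psrf(s, "x") == 1.0

    def test_single_chain_rejected(self):
        s = fake_samples(np.random.default_rng(2).standard_normal((1, 500)))
        with pytest.raises(mcmc.SingleChainError):
            mcmc.gelman_rubin_psrf(s, "x")

    def test_unknown_parameter(self, trait_samples):
        with pytest.raises(mcmc.UnknownParameterError):
            trait_samples.chains("nope")


class TestEffectiveSampleSize:
    def test_white_noise_near_total(self):
        rng = np.random.default_rng(3)
        s = fake_samples(rng.standard_normal((1, 10_000)))
        ess = mcmc.effective_sample_size(s, "x")
        assert 0.9 * 10_000 <= ess <= 10_000

    def test_ar1_closed_form(self):
        rho, n = 0.9, 40_000
        rng = np.random.default_rng(4)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        s = fake_samples(x[None, :])
        expected = n * (1 - rho) / (1 + rho)
        assert mcmc.effective_sample_size(s, "x") == pytest.approx(expected, rel=0.2)

    def test_never_exceeds_total_draws(self, trait_samples):
        for nm in ("intercept", "log_mass"):
            ess = mcmc.effective_sample_size(trait_samples, nm)
            assert 0 < ess <= trait_samples.n_chains * trait_samples.n_per_chain

    def test_constant_chain_total_with_warning(self):
        s = fake_samples(np.full((2, 200), 1.0))
        with pytest.warns(RuntimeWarning, match="constant"):
            assert mcmc.effective_sample_size(s, "x") == 400.0

    def test_short_chain_rejected(self):
        s = fake_samples(np.zeros((1, 50)))
        with pytest.raises(mcmc.MCMCError):
            mcmc.effective_sample_size(s, "x")


def oracle_prior():
    return pm.PriorConfig(include_predator_effect=False, include_overdispersion=False)


class TestGridOracle:
    def test_symmetric_data_centres_mortality_at_half(self):
        table = make_table([("v1", "g", 1, 10, 5)])
        grid = pm.grid_posterior_oracle(table, "predator_effect",
                                        bounds=[(-15, 15)], prior=oracle_prior())
        post_mean_mort = grid.expectation(lambda pts: pm.inverse_logit(pts[:, 0]))
        assert post_mean_mort == pytest.approx(0.5, abs=0.01)
        assert grid.mean("intercept") == pytest.approx(0.0, abs=0.02)

    def test_zero_deaths_mass_below_zero(self):
        table = make_table([("v1", "g", 1, 10, 0)])
        grid = pm.grid_posterior_oracle(table, "predator_effect",
                                        bounds=[(-15, 15)], prior=oracle_prior())
        assert grid.prob(lambda pts: pts[:, 0] < 0) > 0.95

    def test_degenerate_bounds_rejected(self):
        table = make_table([("v1", "g", 1, 10, 5)])
        with pytest.raises(mcmc.OracleError):
            pm.grid_posterior_oracle(table, "predator_effect",
                                     bounds=[(2.0, 2.0)], prior=oracle_prior())

    def test_too_many_free_parameters_rejected(self, predation_table):
        table, _ = predation_table
        small = make_table([("v1", "Notonecta glauca adult", 1, 10, 5)],
                           traits=pm.predator_trait_map())
        with pytest.raises(mcmc.OracleError):
            pm.grid_posterior_oracle(small, "trait_reduced",
                                     bounds=[(-5, 5)] * 4, prior=oracle_prior())

    def test_too_many_observations_rejected(self):
        rows = [(f"v{i}", "g", 1, 10, 5) for i in range(7)]
        with pytest.raises(mcmc.OracleError):
            pm.grid_posterior_oracle(make_table(rows), "predator_effect",
                                     bounds=[(-15, 15)], prior=oracle_prior())

    def test_random_effects_must_be_fixed(self):
        table = make_table([("v1", "g", 1, 10, 5)])
        with pytest.raises(mcmc.OracleError):
            pm.grid_posterior_oracle(table, "predator_effect", bounds=[(-15, 15)],
                                     prior=pm.PriorConfig())


class TestDiagnosticsCrossCheck:
    """Hand-rolled PSRF/ESS agree with arviz on well-behaved chains."""

    def test_against_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        # mildly autocorrelated chains
        raw = rng.standard_normal((4, 4_000))
        x = np.empty_like(raw)
        x[:, 0] = raw[:, 0]
        for t in range(1, raw.shape[1]):
            x[:, t] = 0.5 * x[:, t - 1] + raw[:, t] * np.sqrt(0.75)
        s = fake_samples(x)
        ours_rhat = mcmc.gelman_rubin_psrf(s, "x")
        ours_ess = mcmc.effective_sample_size(s, "x")
        idata = az.from_dict(posterior={"x": x})
        theirs_rhat = float(az.rhat(idata)["x"].values)
        theirs_ess = float(az.ess(idata)["x"].values)
        assert ours_rhat == pytest.approx(theirs_rhat, abs=0.01)
        assert ours_ess == pytest.approx(theirs_ess, rel=0.15)
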