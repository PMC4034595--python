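"""Linear predictors, likelihood and priors of the three mortality models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import predmort as pm
from predmort import models

from conftest import make_table


def reduced_params(**overrides):
    kw = dict(intercept=-3.35, log_mass=1.0, ambush=2.38, suctorial=2.15,
              sigma_predator=1.89, sigma_obs=0.28, variant="reduced")
    kw.update(overrides)
    return pm.TraitModelParams(**kw)


class TestInverseLogit:
    def test_midpoint(self):
        assert pm.inverse_logit(0.0) == 0.5

    @pytest.mark.parametrize("x", [-3.35, -0.97])
    def test_closed_form(self, x):
        assert pm.inverse_logit(x) == pytest.approx(1.0 / (1.0 + math.exp(-x)))

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, x):
        p = pm.inverse_logit(x)
        assert 0.0 < p < 1.0
        assert pm.inverse_logit(-x) == pytest.approx(1.0 - p, abs=1e-12)

    def test_saturates_gracefully(self):
        assert pm.inverse_logit(1e4) == 1.0
        assert pm.inverse_logit(-1e4) == 0.0


class TestCenterLogMass:
    def test_zero_at_mean(self):
        assert pm.center_log_mass([2.0, 2.0, 2.0], 2.0) == pytest.approx(0.0)

    def test_arithmetic(self):
        assert pm.center_log_mass([1.0, 100.0], 1.0) == \
            pytest.approx(math.log(1) - math.log(50.5))

    def test_packaged_masses_center_at_their_mean(self, fixtures):
        _, predators = fixtures
        masses = [p.mass_mg for p in predators]
        assert pm.center_log_mass(masses, np.mean(masses)) == pytest.approx(0.0)
        assert pm.mean_predator_mass() == pytest.approx(np.mean(masses))

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(models.ModelSpecError):
            pm.center_log_mass([1.0, -2.0], 1.0)


class TestLinearPredictor:
    def test_reduced_contrast_sum(self):
        # ambush, chewing predator at mean mass under the reduced point means
        params = reduced_params(log_mass=0.0, suctorial=0.0)
        row = pm.DesignRow(centered_log_mass=0.0, ambush=1, suctorial=0, pelagic=0)
        eta = models.trait_linear_predictor(params, row)
        assert eta == pytest.approx(-3.35 + 2.38)

    def test_quadratic_contribution(self):
        params = pm.TraitModelParams(
            intercept=0.0, log_mass=1.0, log_mass_sq=-0.19, ambush=0.0,
            suctorial=0.0, pelagic=0.0, variant="full",
            sigma_predator=1.0, sigma_obs=1.0)
        row = pm.DesignRow(centered_log_mass=0.5, ambush=0, suctorial=0, pelagic=0)
        assert models.trait_linear_predictor(params, row) == \
            pytest.approx(0.5 + (-0.19) * 0.25)

    def test_prey_intercept_only(self):
        table = make_table([("c1", "Culex sp. larva", 0, 10, 0)], schema="prey_choice")
        params = pm.PreySelectivityParams(
            baseline={"Culex sp. larva": -2.0}, effect={"Culex sp. larva": 0.0},
            sigma_obs=1.0)
        design = pm.build_design(table, "prey_selectivity")
        eta = pm.linear_predictor(design, params)
        assert eta == pytest.approx([-2.0])

    def test_full_equals_reduced_when_extra_terms_zero(self, predation_table):
        table, _ = predation_table
        red = reduced_params()
        full = pm.TraitModelParams(
            intercept=red.intercept, log_mass=red.log_mass, log_mass_sq=0.0,
            ambush=red.ambush, suctorial=red.suctorial, pelagic=0.0,
            variant="full", sigma_predator=red.sigma_predator,
            sigma_obs=red.sigma_obs)
        d_red = pm.build_design(table, "trait_reduced")
        d_full = pm.build_design(table, "trait_full")
        # identical up to summation order of the extra zero-coefficient terms
        np.testing.assert_allclose(pm.linear_predictor(d_red, red),
                                   pm.linear_predictor(d_full, full),
                                   rtol=0, atol=1e-12)

    def test_variant_mismatch_rejected(self, predation_table):
        table, _ = predation_table
        design = pm.build_design(table, "trait_full")
        with pytest.raises(models.ModelSpecError):
            pm.linear_predictor(design, reduced_params())

    def test_reduced_variant_structurally_drops_terms(self):
        with pytest.raises(models.ModelSpecError):
            reduced_params(log_mass_sq=0.0)  # even zero is not allowed


class TestLogLikelihood:
    def test_single_observation_at_half(self):
        table = make_table([("v1", "g", 1, 10, 0)])
        params = pm.PredatorEffectParams(intercept=0.0, predator_effect={"g": 0.0},
                                         sigma_predator=1.0, sigma_obs=1.0)
        expected = math.log(math.comb(10, 0)) + 10 * math.log(0.5)
        assert pm.log_likelihood(table, params, "predator_effect") == \
            pytest.approx(expected)

    def test_symmetry_at_half(self):
        params = pm.PredatorEffectParams(intercept=0.0, predator_effect={"g": 0.0},
                                         sigma_predator=1.0, sigma_obs=1.0)
        t0 = make_table([("v1", "g", 1, 10, 0)])
        t10 = make_table([("v1", "g", 1, 10, 10)])
        assert pm.log_likelihood(t0, params, "predator_effect") == \
            pytest.approx(pm.log_likelihood(t10, params, "predator_effect"))

    def test_additivity(self):
        params = pm.PredatorEffectParams(intercept=-1.0, predator_effect={"g": 0.0},
                                         sigma_predator=1.0, sigma_obs=1.0)
        one = make_table([("v1", "g", 1, 10, 4)])
        two = make_table([("v1", "g", 1, 10, 4), ("v2", "g", 1, 10, 4)])
        assert pm.log_likelihood(two, params, "predator_effect") == \
            pytest.approx(2 * pm.log_likelihood(one, params, "predator_effect"))

    def test_finite_for_extreme_coefficients(self):
        table = make_table([("v1", "g", 1, 10, 10)])
        params = pm.PredatorEffectParams(intercept=-500.0, predator_effect={"g": 0.0},
                                         sigma_predator=1.0, sigma_obs=1.0)
        ll = pm.log_likelihood(table, params, "predator_effect")
        assert np.isfinite(ll)


class TestLogPrior:
    def test_single_coefficient_closed_form(self):
        params = pm.PredatorEffectParams(intercept=0.0, predator_effect={},
                                         sigma_predator=1.0, sigma_obs=1.0)
        lp = pm.log_prior(params, "predator_effect")
        expected = (norm.logpdf(0.0, 0.0, math.sqrt(1e3))
                    + 2 * (math.log(2) + norm.logpdf(1.0, 0.0, 10.0)))
        assert lp == pytest.approx(expected)

    def test_coefficient_additivity(self):
        base = pm.TraitModelParams(intercept=0.0, log_mass=0.0, ambush=0.0,
                                   suctorial=0.0, variant="reduced",
                                   sigma_predator=1.0, sigma_obs=1.0)
        lp = pm.log_prior(base, "trait_reduced")
        coef_term = norm.logpdf(0.0, 0.0, math.sqrt(1e3))
        sd_terms = 2 * (math.log(2) + norm.logpdf(1.0, 0.0, 10.0))
        assert lp == pytest.approx(4 * coef_term + sd_terms)

    @pytest.mark.parametrize("field", ["sigma_predator", "sigma_obs"])
    def test_nonpositive_variance_gives_minus_inf(self, field):
        kw = dict(intercept=0.0, predator_effect={}, sigma_predator=1.0, sigma_obs=1.0)
        kw[field] = -0.5
        params = pm.PredatorEffectParams(**kw)
        assert pm.log_prior(params, "predator_effect") == -np.inf

    def test_prior_dominance_at_extremes(self):
        table = make_table([("v1", "g", 1, 10, 4)])
        posts = []
        for a0 in (0.0, 200.0, 400.0):
            params = pm.PredatorEffectParams(intercept=a0, predator_effect={"g": 0.0},
                                             sigma_predator=1.0, sigma_obs=1.0)
            posts.append(pm.log_posterior(table, params, "predator_effect"))
        assert posts[0] > posts[1] > posts[2]
        assert all(np.isfinite(p) for p in posts)


class TestGrandMeanContract:
    def test_predicted_mortality_is_inverse_logit_of_intercept(self):
        table = make_table([("v1", "g", 1, 10, 4)])
        design = pm.build_design(table, "predator_effect")
        params = pm.PredatorEffectParams(intercept=-1.2, predator_effect={"g": 0.0},
                                         sigma_predator=1.0, sigma_obs=1.0)
        eta = pm.linear_predictor(design, params)
        assert pm.inverse_logit(eta[0]) == pytest.approx(pm.inverse_logit(-1.2))
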