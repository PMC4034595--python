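"""Scikit-learn-style estimators wrapping the Bayesian trial models.

Each estimator holds the chain protocol and prior hyper-parameters as
constructor arguments (so ``get_params``/``set_params``/``clone`` work and
the objects compose with sklearn model selection), fits by MCMC on an
:class:`~predmort.trials.ExperimentTable` (or a raw trial dataframe), and
exposes posterior draws and summaries through trailing-underscore
attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import effects as _effects
from . import summaries as _summaries
from .mcmc import ChainConfig, diagnostics_report, run_chains
from .models import ModelSpecError, PriorConfig, TraitModelParams
from .trials import ExperimentTable, predator_trait_map, table_from_frame


class _BayesianTrialModel(BaseEstimator):
    """Shared fit machinery; subclasses set ``_model_kind`` and ``_schema``."""

    _model_kind: str = ""
    _schema: str = "predation"

    def __init__(self, n_chains=3, n_steps=50_000, thin=10, burn_in=2_000,
                 seed=0, coef_var=1e3, sd_scale=10.0):
        self.n_chains = n_chains
        self.n_steps = n_steps
        self.thin = thin
        self.burn_in = burn_in
        self.seed = seed
        self.coef_var = coef_var
        self.sd_scale = sd_scale

    # -- sklearn plumbing -------------------------------------------------
    def _chain_config(self) -> ChainConfig:
        return ChainConfig(n_chains=self.n_chains, n_steps=self.n_steps,
                           thin=self.thin, burn_in=self.burn_in, seed=self.seed)

    def _prior(self) -> PriorConfig:
        return PriorConfig(coef_var=self.coef_var, sd_scale=self.sd_scale)

    def _as_table(self, X) -> ExperimentTable:
        if isinstance(X, ExperimentTable):
            return X
        if isinstance(X, pd.DataFrame):
            return table_from_frame(X, self._schema, traits=self._traits_for(X))
        raise ModelSpecError("X must be an ExperimentTable or a trial DataFrame")

    def _traits_for(self, X):
        return None

    def fit(self, X, y=None):
        """Run the chains on a trial table; ``y`` is ignored (the response
        lives inside the table)."""
        table = self._as_table(X)
        self.samples_ = run_chains(table, self._model_kind,
                                   prior=self._prior(), config=self._chain_config())
        self.table_ = table
        self.coef_ = {name: float(np.mean(self.samples_.pooled(name)))
                      for name in self.samples_.parameter_names
                      if not name.startswith("predator[")}
        self.n_obs_ = len(table.non_control())
        return self

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise ModelSpecError("estimator is not fitted; call fit() first")

    def diagnostics(self) -> dict:
        self._check_fitted()
        return diagnostics_report(self.samples_)

    def summary(self) -> dict:
        self._check_fitted()
        return _summaries.parameter_table(self.samples_, self.table_)

    def score(self, X=None, y=None) -> float:
        """Fixed-effects explained variance (probability-scale R^2)."""
        self._check_fitted()
        table = self.table_ if X is None else self._as_table(X)
        return _summaries.explained_variance(self.samples_, table,
                                             self._model_kind, at="mean")


class PreySelectivityModel(_BayesianTrialModel):
    """Prey mortality with/without the focal consumer, species-specific."""

    _model_kind = "prey_selectivity"
    _schema = "prey_choice"

    def predict_mortality(self, species: str, treatment: int = 1):
        """Posterior summary of a species' mortality probability."""
        self._check_fitted()
        return _summaries.group_mortality(self.samples_, self._model_kind,
                                          species, treatment=treatment)


class PredatorEffectModel(_BayesianTrialModel):
    """*Sigara* mortality by predator identity (random predator effect)."""

    _model_kind = "predator_effect"

    def _traits_for(self, X):
        return predator_trait_map()

    def predict_mortality(self, predator: str):
        self._check_fitted()
        return _summaries.group_mortality(self.samples_, self._model_kind, predator)


class TraitMortalityModel(_BayesianTrialModel):
    """*Sigara* mortality as a function of predator traits.

    ``variant="full"`` keeps all trait terms; ``variant="reduced"`` drops
    the quadratic mass term and the microhabitat contrast.
    """

    def __init__(self, variant="reduced", n_chains=3, n_steps=50_000, thin=10,
                 burn_in=2_000, seed=0, coef_var=1e3, sd_scale=10.0):
        super().__init__(n_chains=n_chains, n_steps=n_steps, thin=thin,
                         burn_in=burn_in, seed=seed, coef_var=coef_var,
                         sd_scale=sd_scale)
        self.variant = variant

    @property
    def _model_kind(self):
        return f"trait_{self.variant}"

    def _traits_for(self, X):
        return predator_trait_map()

    def _point_params(self) -> TraitModelParams:
        self._check_fitted()
        kw = dict(intercept=self.coef_["intercept"], log_mass=self.coef_["log_mass"],
                  ambush=self.coef_["ambush"], suctorial=self.coef_["suctorial"],
                  sigma_predator=self.coef_["sigma_predator"],
                  sigma_obs=self.coef_["sigma_obs"], variant=self.variant)
        if self.variant == "full":
            kw.update(log_mass_sq=self.coef_["log_mass_sq"],
                      pelagic=self.coef_["pelagic"])
        return TraitModelParams(**kw)

    def predict(self, X) -> np.ndarray:
        """Plug-in mortality probabilities for predators described by their
        traits (DataFrame/records with mass_mg, foraging_mode, feeding_mode,
        microhabitat); random effects are set to zero."""
        self._check_fitted()
        params = self._point_params()
        frame = pd.DataFrame(X)
        out = []
        for rec in frame.itertuples(index=False):
            m = _effects.prediction_curve(
                params, rec.foraging_mode, rec.feeding_mode,
                [float(rec.mass_mg)],
                microhabitat=getattr(rec, "microhabitat", "benthic"),
                mass_center=self.samples_.mass_center, guard=None)
            out.append(float(m[0]))
        return np.asarray(out)

    def mortality_ratio(self, contrast: str, plug_in: bool = True):
        """Fold change in mortality for a trait contrast at mean body mass."""
        self._check_fitted()
        if plug_in:
            return _effects.mortality_ratio_at_mean_mass(self._point_params(), contrast)
        return _effects.posterior_ratio(self.samples_, contrast)

    def prediction_curve(self, foraging: str, feeding: str, mass_grid, **kw):
        self._check_fitted()
        kw.setdefault("mass_center", self.samples_.mass_center)
        return _effects.prediction_curve(self._point_params(), foraging,
                                         feeding, mass_grid, **kw)
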