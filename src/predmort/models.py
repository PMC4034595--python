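"""Overdispersed-binomial mortality models on the logit scale.

All three models share the same two-stage structure.  The number of deaths in
trial *i* is binomial,

.. math:: Y_i \\sim \\mathrm{Bin}(n_i, m_i),

and the mortality probability :math:`m_i` is modelled through a logistic link
with an observation-level Gaussian term :math:`z_i` absorbing extra-binomial
(overdispersion) variance:

* ``prey_selectivity`` — prey mortality with/without the focal consumer,
  species-specific:
  :math:`\\mathrm{logit}(m_i) = a_s + b_s S_i + z_i`, where :math:`a_s` is
  the natural (control) logit-mortality of prey species *s*, :math:`b_s` the
  effect of consumer presence, and :math:`S_i \\in \\{0,1\\}` the treatment
  indicator.  Both are fixed effects; :math:`z_i \\sim N(0, \\sigma^2)`.
* ``predator_effect`` — *Sigara* mortality by predator identity:
  :math:`\\mathrm{logit}(m_i) = a_0 + b_{p(i)} + z_i`, with a random
  predator effect :math:`b_p \\sim N(0, \\sigma_1^2)` and
  :math:`z_i \\sim N(0, \\sigma_2^2)`.
* ``trait_full`` / ``trait_reduced`` — *Sigara* mortality by predator traits:
  the linear predictor adds, on top of the ``predator_effect`` structure,
  a centred-log-mass polynomial and three binary trait contrasts
  (ambush vs searching foraging, suctorial vs chewing feeding, pelagic vs
  benthic microhabitat).  The reduced variant structurally drops the
  quadratic mass term and the microhabitat contrast, whose estimates are
  indistinguishable from zero.

Reference levels are searching / chewing / benthic (indicator 0), so the
intercept is the logit-mortality inflicted by a searching, chewing, benthic
predator of mean body mass.  Body mass enters as
:math:`\\ln w_i - \\ln \\bar w` with :math:`\\bar w` the arithmetic mean of
the predator species' mean masses (unweighted by replicates; configurable).

Priors: every fixed-effect coefficient gets the diffuse
:math:`N(0, 10^3)`; the standard deviations get half-normal(scale 10)
priors, weakly informative and proper.  Latent :math:`b` and :math:`z` are
treated as parameters (sampled, not integrated out).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import norm

from .trials import (CONTROL_LABEL, ExperimentTable, PredatorTraits,
                     predator_trait_map)

MODEL_KINDS = ("prey_selectivity", "predator_effect", "trait_full", "trait_reduced")

#: Names of the trait-contrast coefficients, in design-matrix order.
TRAIT_COEF_NAMES = ("intercept", "log_mass", "log_mass_sq",
                    "ambush", "suctorial", "pelagic")


class ModelSpecError(ValueError):
    """Model kind and supplied data/parameters do not match."""


def inverse_logit(x):
    """Logistic function mapping the linear predictor to a probability.

    Saturates gracefully for large ``|x|`` and satisfies
    ``inverse_logit(-x) == 1 - inverse_logit(x)``.
    """
    return expit(x)


def center_log_mass(masses, w) -> float:
    """Centred log body mass, ``ln(w) - ln(mean(masses))``.

    ``masses`` is the collection of predator mean body masses defining the
    centring point; the result is 0 when ``w`` equals their arithmetic mean.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        raise ModelSpecError("empty mass collection")
    if np.any(masses <= 0) or np.any(np.asarray(w, dtype=float) <= 0):
        raise ModelSpecError("body masses must be strictly positive")
    return np.log(w) - np.log(masses.mean())


def mean_predator_mass(traits: dict[str, PredatorTraits] | None = None) -> float:
    """Arithmetic mean of the predator species' mean body masses (mg)."""
    tmap = predator_trait_map() if traits is None else traits
    return float(np.mean([t.mass_mg for t in tmap.values()]))


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyper-parameters and structural switches.

    coef_var
        Variance of the zero-mean normal prior on every fixed-effect
        coefficient (default the diffuse 10^3).
    sd_scale
        Scale of the half-normal prior on each standard-deviation component.
    include_predator_effect / include_overdispersion
        Structural switches fixing the random predator effect, or the
        observation-level term, at exactly zero (used by the quadrature
        oracle and for degenerate-data checks).
    """

    coef_var: float = 1e3
    sd_scale: float = 10.0
    include_predator_effect: bool = True
    include_overdispersion: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class PreySelectivityParams:
    """Parameters of the prey-choice model.

    ``baseline[s]`` is the natural logit-mortality of prey *s* without the
    consumer; ``effect[s]`` the shift when the consumer is present; ``z`` one
    latent overdispersion value per observation; ``sigma_obs`` its SD.
    """

    baseline: dict[str, float]
    effect: dict[str, float]
    sigma_obs: float
    z: np.ndarray | None = None

    def __post_init__(self):
        # non-positive sigma is representable but outside the prior support:
        # log_prior returns -inf for it rather than raising
        if set(self.baseline) != set(self.effect):
            raise ModelSpecError("baseline and effect must cover the same species")


@dataclass
class PredatorEffectParams:
    """Parameters of the predator-identity model (random predator effect)."""

    intercept: float
    predator_effect: dict[str, float]
    sigma_predator: float
    sigma_obs: float
    z: np.ndarray | None = None


@dataclass
class TraitModelParams:
    """Parameters of the trait-mortality model.

    The ``reduced`` variant has ``log_mass_sq`` and ``pelagic`` structurally
    absent (``None``), not merely zero.
    """

    intercept: float
    log_mass: float
    ambush: float
    suctorial: float
    log_mass_sq: float | None = None
    pelagic: float | None = None
    variant: str = "full"
    predator_effect: dict[str, float] = field(default_factory=dict)
    sigma_predator: float = 1.0
    sigma_obs: float = 1.0
    z: np.ndarray | None = None

    def __post_init__(self):
        if self.variant not in ("full", "reduced"):
            raise ModelSpecError(f"unknown variant {self.variant!r}")
        if self.variant == "reduced":
            if self.log_mass_sq is not None or self.pelagic is not None:
                raise ModelSpecError(
                    "reduced variant must omit log_mass_sq and pelagic entirely")
        else:
            if self.log_mass_sq is None or self.pelagic is None:
                raise ModelSpecError("full variant requires log_mass_sq and pelagic")

    @property
    def coef(self) -> dict[str, float]:
        out = {"intercept": self.intercept, "log_mass": self.log_mass,
               "ambush": self.ambush, "suctorial": self.suctorial}
        if self.variant == "full":
            out["log_mass_sq"] = self.log_mass_sq
            out["pelagic"] = self.pelagic
        return out

    def to_json(self) -> str:
        d = asdict(self)
        if self.z is not None:
            d["z"] = list(np.asarray(self.z, dtype=float))
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "TraitModelParams":
        d = json.loads(s)
        if d.get("z") is not None:
            d["z"] = np.asarray(d["z"], dtype=float)
        return cls(**d)


@dataclass(frozen=True)
class DesignRow:
    """Covariates of a single predation trial for the trait model."""

    centered_log_mass: float
    ambush: int
    suctorial: int
    pelagic: int
    predator_index: str = ""

    def __post_init__(self):
        for f in ("ambush", "suctorial", "pelagic"):
            if getattr(self, f) not in (0, 1):
                raise ModelSpecError(f"indicator {f} must be 0/1")


def design_row(traits: PredatorTraits, mass_center: float | None = None,
               all_traits: dict[str, PredatorTraits] | None = None) -> DesignRow:
    """Build a trait-model design row from a predator's traits."""
    if mass_center is None:
        mass_center = mean_predator_mass(all_traits)
    return DesignRow(
        centered_log_mass=float(np.log(traits.mass_mg) - np.log(mass_center)),
        ambush=int(traits.foraging_mode == "ambush"),
        suctorial=int(traits.feeding_mode == "suctorial"),
        pelagic=int(traits.microhabitat == "pelagic"),
        predator_index=traits.name,
    )


# ---------------------------------------------------------------------------
# Design construction shared by the sampler, the simulator and the summaries


@dataclass
class ModelDesign:
    """Numeric design of one model on one table.

    ``X`` holds the fixed-effect columns; ``group_index`` maps each
    observation to its predator (``None`` for the prey-choice model, whose
    per-species terms are fixed effects inside ``X``).
    """

    kind: str
    coef_names: list[str]
    X: np.ndarray
    n: np.ndarray
    y: np.ndarray
    group_names: list[str]
    group_index: np.ndarray | None
    has_group: bool
    mass_center: float | None = None

    @property
    def n_obs(self) -> int:
        return len(self.n)

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)


def build_design(table: ExperimentTable, model: str,
                 prior: PriorConfig | None = None,
                 mass_center: float | None = None) -> ModelDesign:
    """Turn a validated trial table into the numeric design for ``model``.

    Predator-side models are fitted to predator trials only; control rows
    (which have no predator) are dropped here.  The prey-choice model keeps
    every row and encodes treatment through the per-species effect columns.
    """
    if model not in MODEL_KINDS:
        raise ModelSpecError(f"unknown model {model!r}")
    prior = prior or PriorConfig()

    if model == "prey_selectivity":
        obs = table.observations
        species = table.group_labels()
        if not species:
            return ModelDesign(model, [], np.empty((0, 0)), np.empty(0, int),
                               np.empty(0, int), [], None, has_group=False)
        sidx = {s: j for j, s in enumerate(species)}
        p = 2 * len(species)
        X = np.zeros((len(obs), p))
        names = [f"baseline[{s}]" for s in species] + [f"effect[{s}]" for s in species]
        for i, o in enumerate(obs):
            j = sidx[o.group_label]
            X[i, j] = 1.0
            X[i, len(species) + j] = float(o.treatment)
        n = np.array([o.n_initial for o in obs], dtype=int)
        y = np.array([o.n_dead for o in obs], dtype=int)
        return ModelDesign(model, names, X, n, y, [], None, has_group=False)

    # predator-side models: drop controls, resolve traits where needed
    obs = [o for o in table.observations if o.group_label != CONTROL_LABEL]
    groups = []
    for o in obs:
        if o.group_label not in groups:
            groups.append(o.group_label)
    gidx = {g: j for j, g in enumerate(groups)}
    group_index = np.array([gidx[o.group_label] for o in obs], dtype=int)
    n = np.array([o.n_initial for o in obs], dtype=int)
    y = np.array([o.n_dead for o in obs], dtype=int)

    if model == "predator_effect":
        X = np.ones((len(obs), 1))
        return ModelDesign(model, ["intercept"], X, n, y, groups, group_index,
                           has_group=prior.include_predator_effect)

    tmap = table.traits if table.traits is not None else predator_trait_map()
    missing = [g for g in groups if g not in tmap]
    if missing:
        raise ModelSpecError(f"trait model needs traits for group(s): {missing}")
    if mass_center is None:
        mass_center = mean_predator_mass(tmap)
    clm = np.array([np.log(tmap[g].mass_mg) - np.log(mass_center) for g in groups])
    amb = np.array([float(tmap[g].foraging_mode == "ambush") for g in groups])
    suc = np.array([float(tmap[g].feeding_mode == "suctorial") for g in groups])
    pel = np.array([float(tmap[g].microhabitat == "pelagic") for g in groups])
    per_group = {"intercept": np.ones(len(groups)), "log_mass": clm,
                 "log_mass_sq": clm ** 2, "ambush": amb,
                 "suctorial": suc, "pelagic": pel}
    if model == "trait_reduced":
        names = ["intercept", "log_mass", "ambush", "suctorial"]
    else:
        names = list(TRAIT_COEF_NAMES)
    X = np.column_stack([per_group[c][group_index] for c in names])
    return ModelDesign(model, names, X, n, y, groups, group_index,
                       has_group=prior.include_predator_effect,
                       mass_center=mass_center)


# ---------------------------------------------------------------------------
# Linear predictor / likelihood / prior


def _params_to_vectors(design: ModelDesign, params) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a parameter container onto (beta, b-per-group, z)."""
    kind = design.kind
    if kind == "prey_selectivity":
        if not isinstance(params, PreySelectivityParams):
            raise ModelSpecError("prey_selectivity requires PreySelectivityParams")
        species = [nm[len("baseline["):-1] for nm in design.coef_names
                   if nm.startswith("baseline[")]
        try:
            beta = np.array([params.baseline[s] for s in species]
                            + [params.effect[s] for s in species], dtype=float)
        except KeyError as k:
            raise ModelSpecError(f"missing species in params: {k}") from None
        b = np.zeros(0)
    elif kind == "predator_effect":
        if not isinstance(params, PredatorEffectParams):
            raise ModelSpecError("predator_effect requires PredatorEffectParams")
        beta = np.array([params.intercept], dtype=float)
        b = np.array([params.predator_effect.get(g, 0.0) for g in design.group_names])
    else:
        if not isinstance(params, TraitModelParams):
            raise ModelSpecError("trait models require TraitModelParams")
        want_reduced = design.kind == "trait_reduced"
        if want_reduced != (params.variant == "reduced"):
            raise ModelSpecError(
                f"params variant {params.variant!r} does not match model {design.kind!r}")
        coef = params.coef
        beta = np.array([coef[c] for c in design.coef_names], dtype=float)
        b = np.array([params.predator_effect.get(g, 0.0) for g in design.group_names])
    z = np.zeros(design.n_obs) if getattr(params, "z", None) is None \
        else np.asarray(params.z, dtype=float)
    if z.shape != (design.n_obs,):
        raise ModelSpecError(
            f"z has length {z.size}, expected one per observation ({design.n_obs})")
    return beta, b, z


def linear_predictor(design: ModelDesign, params) -> np.ndarray:
    """Per-observation linear predictor, including ``b`` and ``z`` terms."""
    beta, b, z = _params_to_vectors(design, params)
    eta = design.X @ beta + z
    if design.group_index is not None and b.size:
        eta = eta + b[design.group_index]
    return eta


def trait_linear_predictor(params: TraitModelParams, row: DesignRow,
                           include_predator_effect: bool = True,
                           z: float = 0.0) -> float:
    """Trait-model linear predictor for a single design row."""
    eta = params.intercept + params.log_mass * row.centered_log_mass \
        + params.ambush * row.ambush + params.suctorial * row.suctorial
    if params.variant == "full":
        eta += params.log_mass_sq * row.centered_log_mass ** 2 \
            + params.pelagic * row.pelagic
    if include_predator_effect and row.predator_index:
        eta += params.predator_effect.get(row.predator_index, 0.0)
    return float(eta + z)


def binomial_loglik(y, n, eta) -> float:
    """Binomial log-likelihood at logit-scale success parameter ``eta``."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    eta = np.asarray(eta, float)
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(const + y * eta - n * np.logaddexp(0.0, eta)))


def log_likelihood(table: ExperimentTable, params, model: str,
                   prior: PriorConfig | None = None) -> float:
    """Joint binomial log-likelihood of the table given latent ``z`` values."""
    design = build_design(table, model, prior=prior)
    eta = linear_predictor(design, params)
    return binomial_loglik(design.y, design.n, eta)


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0) + norm.logpdf(x, 0.0, scale)


def log_prior(params, model: str, prior: PriorConfig | None = None) -> float:
    """Joint log prior density, including the hierarchical terms.

    Coefficients: N(0, ``coef_var``).  Random effects: ``b ~ N(0,
    sigma_predator^2)``, ``z ~ N(0, sigma_obs^2)``.  SDs: half-normal.
    Non-positive variance components yield ``-inf`` (rejected), not an
    exception.
    """
    prior = prior or PriorConfig()
    coef_sd = math.sqrt(prior.coef_var)
    lp = 0.0
    if model == "prey_selectivity":
        coefs = list(params.baseline.values()) + list(params.effect.values())
        sig_obs, sig_pred, b = params.sigma_obs, None, None
    elif model == "predator_effect":
        coefs = [params.intercept]
        sig_obs, sig_pred = params.sigma_obs, params.sigma_predator
        b = list(params.predator_effect.values())
    else:
        coefs = list(params.coef.values())
        sig_obs, sig_pred = params.sigma_obs, params.sigma_predator
        b = list(params.predator_effect.values())
    lp += float(np.sum(norm.logpdf(coefs, 0.0, coef_sd)))
    if sig_pred is not None:
        if sig_pred <= 0:
            return -np.inf
        lp += _half_normal_logpdf(sig_pred, prior.sd_scale)
        if b:
            lp += float(np.sum(norm.logpdf(b, 0.0, sig_pred)))
    if sig_obs <= 0:
        return -np.inf
    lp += _half_normal_logpdf(sig_obs, prior.sd_scale)
    z = getattr(params, "z", None)
    if z is not None:
        lp += float(np.sum(norm.logpdf(np.asarray(z, float), 0.0, sig_obs)))
    return lp


def log_posterior(table: ExperimentTable, params, model: str,
                  prior: PriorConfig | None = None) -> float:
    lp = log_prior(params, model, prior)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(table, params, model, prior)
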