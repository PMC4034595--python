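"""Posterior summaries: parameter tables, group mortality, explained variance.

Summaries pool the post-burn-in draws of all chains.  Quantiles use linear
interpolation of the empirical CDF (numpy's default), the Monte-Carlo
standard error of the mean uses non-overlapping batch means with
floor(sqrt(N)) batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mcmc import PosteriorSamples, UnknownParameterError
from .models import ModelSpecError, build_design, inverse_logit
from .trials import CONTROL_LABEL, ExperimentTable


@dataclass(frozen=True)
class ParameterSummary:
    name: str
    mean: float
    mcse: float
    median: float
    ci95: tuple[float, float]
    sd: float = float("nan")
    n_draws: int = 0

    def to_dict(self) -> dict:
        return {"name": self.name, "mean": self.mean, "mcse": self.mcse,
                "sd": self.sd, "median": self.median,
                "ci95": list(self.ci95), "n_draws": self.n_draws}


def batch_means_mcse(draws: np.ndarray) -> float:
    """MCSE of the mean from floor(sqrt(N)) non-overlapping batches."""
    x = np.asarray(draws, float).reshape(-1)
    nb = int(np.floor(np.sqrt(x.size)))
    if nb < 2:
        return float(np.std(x, ddof=0) / np.sqrt(max(x.size, 1)))
    size = x.size // nb
    means = x[:nb * size].reshape(nb, size).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(nb))


def summarize_draws(draws: np.ndarray, name: str = "") -> ParameterSummary:
    x = np.asarray(draws, float).reshape(-1)
    if x.size == 0:
        raise ModelSpecError("no draws to summarize")
    lo, hi = np.quantile(x, [0.025, 0.975])  # linear-interpolation quantiles
    return ParameterSummary(
        name=name, mean=float(np.mean(x)), mcse=batch_means_mcse(x),
        median=float(np.median(x)), ci95=(float(lo), float(hi)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0, n_draws=x.size)


def summarize(samples: PosteriorSamples, parameter: str) -> ParameterSummary:
    """Mean, batch-means MCSE, median and equal-tailed 95% CI of a parameter."""
    return summarize_draws(samples.pooled(parameter), name=parameter)


def group_mortality(samples: PosteriorSamples, model: str, group: str,
                    treatment: int = 1) -> ParameterSummary:
    """Posterior mortality probability of a group (z set to 0, b included).

    Prey-choice model: ``group`` is the prey species and ``treatment`` marks
    consumer presence.  Predator model: ``group`` is the predator, whose
    random effect is added to the intercept.
    """
    if model == "prey_selectivity":
        eta = samples.pooled(f"baseline[{group}]").copy()
        if treatment:
            eta += samples.pooled(f"effect[{group}]")
    elif model == "predator_effect":
        if group == CONTROL_LABEL:
            raise UnknownParameterError("controls have no predator effect")
        eta = samples.pooled("intercept") + samples.pooled(f"predator[{group}]")
    else:
        raise ModelSpecError(f"group_mortality supports prey_selectivity or "
                             f"predator_effect, not {model!r}")
    return summarize_draws(inverse_logit(eta), name=f"mortality[{group},S={treatment}]")


def control_mortality(samples: PosteriorSamples) -> ParameterSummary:
    """Mortality implied by the intercept alone with the random effect at 0."""
    eta = samples.pooled("intercept")
    return summarize_draws(inverse_logit(eta), name="mortality[intercept]")


def _point_coefs(samples_or_params, names: list[str], at: str) -> np.ndarray:
    if isinstance(samples_or_params, PosteriorSamples):
        if at == "mean":
            return np.array([float(np.mean(samples_or_params.pooled(nm))) for nm in names])
        if at == "median":
            return np.array([float(np.median(samples_or_params.pooled(nm))) for nm in names])
        raise ModelSpecError(f"at must be 'mean' or 'median', got {at!r}")
    coef = samples_or_params  # mapping name -> value
    try:
        return np.array([float(coef[nm]) for nm in names])
    except (KeyError, TypeError) as err:
        raise ModelSpecError(f"cannot evaluate coefficients: {err}") from None


def explained_variance(samples_or_params, table: ExperimentTable, model: str,
                       at: str = "mean") -> float:
    """Fixed-effects-only R-squared on the probability scale.

    Observed per-trial death proportions are compared with the inverse-logit
    of the fixed-effect linear predictor evaluated at the posterior mean (or
    median) coefficients; random predator effects and overdispersion terms
    are excluded from the fit, so the value measures what the traits alone
    explain.  Undefined (NaN, with a warning) when the observed proportions
    have zero variance.
    """
    design = build_design(table, model)
    beta = _point_coefs(samples_or_params, list(design.coef_names), at)
    obs = design.y / design.n
    fit = inverse_logit(design.X @ beta)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("observed proportions are constant; explained variance undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    sse = float(np.sum((obs - fit) ** 2))
    return 1.0 - sse / sst


def parameter_table(samples: PosteriorSamples, table: ExperimentTable | None = None) -> dict:
    """Report shaped like the published estimate table.

    One row per fixed-effect coefficient plus the interspecific
    (among-predator) and intraspecific (trial-level) SDs, each as
    ``mean (MCSE)`` and ``median (95% CI)``; explained variance at the
    posterior mean and median when a data table is supplied.
    """
    rows = []
    for name in samples.parameter_names:
        if name.startswith("predator["):
            continue
        s = summarize(samples, name)
        label = {"sigma_predator": "SD interspecific",
                 "sigma_obs": "SD intraspecific"}.get(name, name)
        rows.append({"parameter": label, **s.to_dict()})
    report = {"model": samples.model, "rows": rows}
    if table is not None:
        try:
            report["explained_variance"] = {
                at: explained_variance(samples, table, samples.model, at=at)
                for at in ("mean", "median")}
        except ModelSpecError:
            pass
    return report


def format_parameter_table(report: dict) -> str:
    """Aligned plain-text rendering of :func:`parameter_table` output."""
    lines = [f"model: {report['model']}",
             f"{'parameter':<28}{'mean (MCSE)':>20}  {'median (95% CI)':>30}"]
    for row in report["rows"]:
        mean = f"{row['mean']:.2f} ({row['mcse']:.3f})"
        med = f"{row['median']:.2f} ({row['ci95'][0]:.2f}, {row['ci95'][1]:.2f})"
        lines.append(f"{row['parameter']:<28}{mean:>20}  {med:>30}")
    ev = report.get("explained_variance")
    if ev is not None:
        lines.append(f"{'Explained variance (%)':<28}"
                     f"{100 * ev['mean']:>19.1f}%  {100 * ev['median']:>29.1f}%")
    return "\n".join(lines)
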