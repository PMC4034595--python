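"""Adaptive Metropolis-within-Gibbs sampling and convergence diagnostics.

The posterior of every model is explored with component-wise random-walk
Metropolis updates cycling over four blocks: fixed-effect coefficients,
per-predator random effects, observation-level overdispersion terms, and
(log-scale) standard-deviation components.  Random-effect and
observation-level components touch disjoint slices of the likelihood, so
their proposals are accepted or rejected independently in parallel — each
component behaves as a scalar update.

Proposal scales adapt by Robbins-Monro recursion toward 0.44 acceptance
during the burn-in/adaptation phase only; retained draws always come from a
fixed kernel, preserving detailed balance.  The chain protocol mirrors the
original analysis: burn-in first, then the sampling phase whose every
``thin``-th state is retained, so the default configuration
(3 chains x 10^6 sampling steps, thinning 100, burn-in 2x10^3) keeps exactly
10^4 draws per chain.

A brute-force quadrature oracle over 1-2 free coefficients provides an
MCMC-independent check of posterior moments on tiny instances.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import ModelDesign, PriorConfig, build_design
from .trials import ExperimentTable

ACCEPT_TARGET = 0.44


class MCMCError(ValueError):
    """Sampler precondition or configuration failure."""


class ChainConfigError(MCMCError):
    """Invalid chain configuration."""


class SingleChainError(MCMCError):
    """A multi-chain diagnostic was asked of a single chain."""


class UnknownParameterError(KeyError):
    """Requested parameter is not in the posterior sample."""


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain protocol.

    ``n_steps`` counts post-burn-in sampling iterations; every ``thin``-th
    state of those is retained, so ``n_steps // thin`` draws are kept per
    chain.  ``burn_in`` iterations (during which proposal scales adapt) run
    first and are discarded.
    """

    n_chains: int = 3
    n_steps: int = 1_000_000
    thin: int = 100
    burn_in: int = 2_000
    seed: int = 0
    adapt_steps: int | None = None  # defaults to burn_in

    def __post_init__(self):
        if self.n_chains < 1:
            raise ChainConfigError("need at least one chain")
        if self.thin < 1:
            raise ChainConfigError("thin must be positive")
        if self.n_steps < self.thin:
            raise ChainConfigError("no retained draws: n_steps < thin")
        if self.n_steps % self.thin:
            raise ChainConfigError("thin must divide n_steps")
        if self.burn_in < 0:
            raise ChainConfigError("burn_in must be non-negative")

    @property
    def n_retained_per_chain(self) -> int:
        return self.n_steps // self.thin

    @property
    def n_adapt(self) -> int:
        return self.burn_in if self.adapt_steps is None else self.adapt_steps

    @classmethod
    def test_scale(cls, seed: int = 0, **kw) -> "ChainConfig":
        """Desk-scale protocol (5x10^4 steps, thin 10) for quick runs."""
        kw.setdefault("n_steps", 50_000)
        kw.setdefault("thin", 10)
        kw.setdefault("burn_in", 2_000)
        return cls(seed=seed, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorSamples:
    """Thinned multi-chain posterior draws with provenance.

    ``draws`` maps parameter name to a ``(n_chains, n_retained)`` array.
    """

    draws: dict[str, np.ndarray]
    config: ChainConfig
    model: str
    prior: PriorConfig = field(default_factory=PriorConfig)
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    group_names: list[str] = field(default_factory=list)
    mass_center: float | None = None

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_per_chain(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def chains(self, parameter: str) -> np.ndarray:
        try:
            return self.draws[parameter]
        except KeyError:
            raise UnknownParameterError(parameter) from None

    def pooled(self, parameter: str) -> np.ndarray:
        """All chains concatenated (draws are already post burn-in)."""
        return self.chains(parameter).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        c, s = self.n_chains, self.n_per_chain
        out = {"chain": np.repeat(np.arange(c), s),
               "iteration": np.tile(np.arange(s), c)}
        for name, arr in self.draws.items():
            out[name] = arr.reshape(-1)
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        meta = {"model": self.model, "config": self.config.to_dict(),
                "prior": self.prior.to_dict(),
                "acceptance_rates": self.acceptance_rates,
                "group_names": self.group_names,
                "mass_center": self.mass_center}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# predmort-posterior {json.dumps(meta)}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorSamples":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("# predmort-posterior "):
                raise MCMCError(f"{path} is not a posterior-sample file")
            meta = json.loads(header[len("# predmort-posterior "):])
            frame = pd.read_csv(fh)
        cfg = ChainConfig(**meta["config"])
        n_chains = int(frame["chain"].max()) + 1
        draws = {}
        for name in frame.columns:
            if name in ("chain", "iteration"):
                continue
            draws[name] = frame[name].to_numpy().reshape(n_chains, -1)
        return cls(draws=draws, config=cfg, model=meta["model"],
                   prior=PriorConfig.from_dict(meta["prior"]),
                   acceptance_rates=meta.get("acceptance_rates", {}),
                   group_names=meta.get("group_names", []),
                   mass_center=meta.get("mass_center"))


# ---------------------------------------------------------------------------
# sampler


def _ll_terms(y, n, eta):
    # binomial log-likelihood up to the constant binomial coefficient
    return y * eta - n * np.logaddexp(0.0, eta)


class _ChainState:
    """One chain's state and adaptive proposal scales."""

    def __init__(self, design: ModelDesign, prior: PriorConfig, rng: np.random.Generator):
        self.design = design
        self.prior = prior
        self.rng = rng
        p, G, N = design.n_coef, design.n_groups, design.n_obs
        self.beta = np.zeros(p)
        self.has_group = design.has_group
        self.has_z = prior.include_overdispersion
        self.b = np.zeros(G)
        self.z = np.zeros(N)
        self.log_sg = 0.0  # sd of predator effects, log scale
        self.log_so = 0.0  # sd of observation effects, log scale
        self.eta = design.X @ self.beta if p else np.zeros(N)
        if self.has_group and G:
            self.eta = self.eta + self.b[design.group_index]
        self.ll_obs = _ll_terms(design.y, design.n, self.eta)
        self.cur_ll = float(np.sum(self.ll_obs))
        if not np.isfinite(self.cur_ll):
            raise MCMCError("non-finite posterior at initial state")
        # per-block proposal scales
        self.s_beta = np.full(p, 1.0)
        self.s_b = 0.5
        self.s_z = 0.5
        self.s_sg = 0.5
        self.s_so = 0.5
        self.acc = {k: 0 for k in ("coef", "predator", "obs", "sd")}
        self.tries = {k: 0 for k in ("coef", "predator", "obs", "sd")}

    # -- single sweep over all blocks ------------------------------------
    def sweep(self, adapt_gamma: float | None) -> None:
        d, rng = self.design, self.rng
        y, n = d.y, d.n
        coef_var = self.prior.coef_var
        scale2 = self.prior.sd_scale ** 2

        for j in range(d.n_coef):
            step = self.s_beta[j] * rng.standard_normal()
            new = self.beta[j] + step
            eta_new = self.eta + d.X[:, j] * step
            ll_obs_new = _ll_terms(y, n, eta_new)
            ll_new = float(np.sum(ll_obs_new))
            dlp = (self.beta[j] ** 2 - new ** 2) / (2.0 * coef_var)
            accepted = math.log(rng.random()) < ll_new - self.cur_ll + dlp
            if accepted:
                self.beta[j] = new
                self.eta = eta_new
                self.ll_obs = ll_obs_new
                self.cur_ll = ll_new
            self.tries["coef"] += 1
            self.acc["coef"] += accepted
            if adapt_gamma is not None:
                self.s_beta[j] *= math.exp(adapt_gamma * (accepted - ACCEPT_TARGET))

        if self.has_group and d.n_groups:
            gi = d.group_index
            dz = self.s_b * rng.standard_normal(d.n_groups)
            eta_new = self.eta + dz[gi]
            ll_obs_new = _ll_terms(y, n, eta_new)
            dll_obs = ll_obs_new - self.ll_obs
            dll_g = np.bincount(gi, weights=dll_obs, minlength=d.n_groups)
            sg2 = math.exp(2.0 * self.log_sg)
            dlp_g = (self.b ** 2 - (self.b + dz) ** 2) / (2.0 * sg2)
            accept = np.log(rng.random(d.n_groups)) < dll_g + dlp_g
            if np.any(accept):
                self.b = self.b + dz * accept
                acc_obs = accept[gi]
                self.eta = np.where(acc_obs, eta_new, self.eta)
                self.ll_obs = np.where(acc_obs, ll_obs_new, self.ll_obs)
                self.cur_ll = float(np.sum(self.ll_obs))
            rate = float(np.mean(accept))
            self.tries["predator"] += 1
            self.acc["predator"] += rate
            if adapt_gamma is not None:
                self.s_b *= math.exp(adapt_gamma * (rate - ACCEPT_TARGET))

        if self.has_z and d.n_obs:
            dz = self.s_z * rng.standard_normal(d.n_obs)
            eta_new = self.eta + dz
            ll_obs_new = _ll_terms(y, n, eta_new)
            dll = ll_obs_new - self.ll_obs
            so2 = math.exp(2.0 * self.log_so)
            dlp = (self.z ** 2 - (self.z + dz) ** 2) / (2.0 * so2)
            accept = np.log(rng.random(d.n_obs)) < dll + dlp
            if np.any(accept):
                self.z = self.z + dz * accept
                self.eta = np.where(accept, eta_new, self.eta)
                self.ll_obs = np.where(accept, ll_obs_new, self.ll_obs)
                self.cur_ll = float(np.sum(self.ll_obs))
            rate = float(np.mean(accept))
            self.tries["obs"] += 1
            self.acc["obs"] += rate
            if adapt_gamma is not None:
                self.s_z *= math.exp(adapt_gamma * (rate - ACCEPT_TARGET))

        # sd components: random walk on log(sd) with Jacobian term (+l)
        if self.has_group:
            self.log_sg, self.s_sg = self._sd_update(
                self.log_sg, self.s_sg, float(np.sum(self.b ** 2)),
                self.b.size, scale2, adapt_gamma)
        if self.has_z:
            self.log_so, self.s_so = self._sd_update(
                self.log_so, self.s_so, float(np.sum(self.z ** 2)),
                self.z.size, scale2, adapt_gamma)

    def _sd_update(self, l, s, ssq, k, scale2, adapt_gamma):
        def logpost(l_):
            sig2 = math.exp(2.0 * l_)
            return -k * l_ - ssq / (2.0 * sig2) - sig2 / (2.0 * scale2) + l_

        prop = l + s * self.rng.standard_normal()
        accepted = math.log(self.rng.random()) < logpost(prop) - logpost(l)
        if accepted:
            l = prop
        self.tries["sd"] += 1
        self.acc["sd"] += accepted
        if adapt_gamma is not None:
            s *= math.exp(adapt_gamma * (accepted - ACCEPT_TARGET))
        return l, s

    def snapshot(self) -> np.ndarray:
        vals = [self.beta]
        if self.has_group and self.design.n_groups:
            vals.append(self.b)
        if self.has_group:
            vals.append([math.exp(self.log_sg)])
        if self.has_z:
            vals.append([math.exp(self.log_so)])
        return np.concatenate([np.atleast_1d(np.asarray(v, float)) for v in vals])

    def snapshot_names(self) -> list[str]:
        names = list(self.design.coef_names)
        if self.has_group and self.design.n_groups:
            names += [f"predator[{g}]" for g in self.design.group_names]
        if self.has_group:
            names.append("sigma_predator")
        if self.has_z:
            names.append("sigma_obs")
        return names


def run_chains(table: ExperimentTable, model: str,
               prior: PriorConfig | None = None,
               config: ChainConfig | None = None) -> PosteriorSamples:
    """Sample the posterior of ``model`` on ``table``.

    Identical ``config`` (including seed) gives bit-identical draws.  The
    prey-choice model has no predator random effect; predator-side models
    ignore control rows.  All-zero or all-``n`` death patterns are valid —
    the prior regularizes them.
    """
    prior = prior or PriorConfig()
    config = config or ChainConfig()
    design = build_design(table, model, prior=prior)
    # sigma_predator only exists for models with a predator random effect
    if model == "prey_selectivity":
        design.has_group = False

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(config.n_chains)]
    per_chain = []
    names = None
    accept = {}
    for ci, rng in enumerate(streams):
        state = _ChainState(design, prior, rng)
        names = state.snapshot_names()
        n_adapt = config.n_adapt
        total_warm = max(config.burn_in, n_adapt)
        for t in range(total_warm):
            gamma = (t + 1) ** -0.6 if t < n_adapt else None
            state.sweep(gamma)
        kept = np.empty((config.n_retained_per_chain, len(names)))
        k = 0
        for t in range(config.n_steps):
            state.sweep(None)
            if (t + 1) % config.thin == 0:
                kept[k] = state.snapshot()
                k += 1
        per_chain.append(kept)
        for blk in state.tries:
            if state.tries[blk]:
                accept[f"{blk}/chain{ci}"] = state.acc[blk] / state.tries[blk]

    stacked = np.stack(per_chain)  # (chains, samples, params)
    draws = {nm: np.ascontiguousarray(stacked[:, :, j]) for j, nm in enumerate(names or [])}
    return PosteriorSamples(draws=draws, config=config, model=model, prior=prior,
                            acceptance_rates=accept, group_names=list(design.group_names),
                            mass_center=design.mass_center)


# ---------------------------------------------------------------------------
# convergence diagnostics


def gelman_rubin_psrf(samples: PosteriorSamples, parameter: str) -> float:
    """Split-chain potential scale reduction factor (values near 1 = mixed).

    Each chain is split in half; the PSRF compares between- and within-split
    variances.  Identical constant chains return 1.0 by convention (the
    statistic is otherwise undefined there).
    """
    x = samples.chains(parameter)
    if x.shape[0] < 2:
        raise SingleChainError("PSRF needs at least two chains")
    half = x.shape[1] // 2
    if half < 2:
        raise MCMCError("chains too short to split")
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    L = splits.shape[1]
    w = float(np.mean(np.var(splits, axis=1, ddof=1)))
    var_means = float(np.var(np.mean(splits, axis=1), ddof=1))
    if w == 0.0:
        return 1.0 if var_means == 0.0 else float("inf")
    var_hat = (L - 1) / L * w + var_means
    return float(np.sqrt(var_hat / w))


def _chain_ess(x: np.ndarray) -> float:
    L = x.size
    x = x - x.mean()
    var = float(np.dot(x, x)) / L
    if var == 0.0:
        return float(L)
    nfft = 1 << (2 * L - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:L] / L
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < L:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(L, max(1.0, L / tau)))


def effective_sample_size(samples: PosteriorSamples, parameter: str) -> float:
    """Autocorrelation-based ESS (Geyer initial positive sequence), summed
    over chains.  A constant parameter has no autocorrelation structure; its
    ESS is reported as the total draw count with a warning.
    """
    x = samples.chains(parameter)
    total = x.size
    if total < 100:
        raise MCMCError("need at least 100 retained draws for ESS")
    if np.ptp(x) == 0.0:
        warnings.warn(f"parameter {parameter!r} is constant; ESS set to total draws",
                      RuntimeWarning, stacklevel=2)
        return float(total)
    return float(sum(_chain_ess(row) for row in x))


def diagnostics_report(samples: PosteriorSamples) -> dict:
    """PSRF and ESS for every retained parameter, as a JSON-able dict."""
    out = {}
    for name in samples.parameter_names:
        out[name] = {"psrf": gelman_rubin_psrf(samples, name),
                     "ess": effective_sample_size(samples, name)}
    return out


# ---------------------------------------------------------------------------
# quadrature oracle


class OracleError(ValueError):
    """Grid-oracle precondition failure."""


@dataclass
class GridPosterior:
    """Normalized posterior over a small coefficient grid."""

    coef_names: list[str]
    points: np.ndarray   # (M, p)
    weights: np.ndarray  # (M,), sums to 1

    def _col(self, name: str) -> np.ndarray:
        try:
            j = self.coef_names.index(name)
        except ValueError:
            raise UnknownParameterError(name) from None
        return self.points[:, j]

    def mean(self, name: str) -> float:
        return float(np.sum(self.weights * self._col(name)))

    def sd(self, name: str) -> float:
        c = self._col(name)
        m = self.mean(name)
        return float(np.sqrt(np.sum(self.weights * (c - m) ** 2)))

    def expectation(self, func) -> float:
        """Posterior expectation of ``func(points_row)`` (vectorized over rows)."""
        vals = func(self.points)
        return float(np.sum(self.weights * np.asarray(vals, float)))

    def prob(self, predicate) -> float:
        mask = np.asarray(predicate(self.points), bool)
        return float(np.sum(self.weights[mask]))


def grid_posterior_oracle(table: ExperimentTable, model: str,
                          bounds: list[tuple[float, float]],
                          resolution: int = 2001,
                          prior: PriorConfig | None = None) -> GridPosterior:
    """Brute-force quadrature of the posterior with random effects fixed at 0.

    Only models with at most two free coefficients and at most six
    observations are supported — this is a verification oracle for the MCMC
    sampler, not an inference method.
    """
    prior = prior or PriorConfig(include_predator_effect=False,
                                 include_overdispersion=False)
    if prior.include_predator_effect or prior.include_overdispersion:
        raise OracleError("oracle requires b and z fixed at zero "
                          "(include_* flags must be False)")
    design = build_design(table, model, prior=prior)
    if design.n_obs > 6:
        raise OracleError("oracle limited to six observations")
    p = design.n_coef
    if p == 0 or p > 2:
        raise OracleError("oracle supports one or two free coefficients")
    if len(bounds) != p:
        raise OracleError(f"need {p} bounds, got {len(bounds)}")
    axes = []
    for lo, hi in bounds:
        if not hi > lo:
            raise OracleError(f"degenerate bounds ({lo}, {hi})")
        axes.append(np.linspace(lo, hi, resolution))
    if p == 1:
        points = axes[0][:, None]
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        points = np.column_stack([g0.ravel(), g1.ravel()])
    eta = points @ design.X.T  # (M, n_obs)
    ll = np.sum(design.y * eta - design.n * np.logaddexp(0.0, eta), axis=1)
    lp = -np.sum(points ** 2, axis=1) / (2.0 * prior.coef_var)
    logpost = ll + lp
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return GridPosterior(list(design.coef_names), points, w)
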