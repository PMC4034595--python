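# Methods

## The models

`predmort` analyses 24-hour predation trials in which a known number of
individuals is exposed in a vessel and the dead are counted. All three
models share a two-stage overdispersed-binomial core: deaths are binomial,
`Y_i ~ Bin(n_i, m_i)`, and the mortality `m_i` is modelled on the logit
scale with an observation-level Gaussian term `z_i ~ N(0, σ_obs²)` that
absorbs extra-binomial variance. `z_i` (and the predator effects `b`) are
latent parameters that the sampler draws; nothing is integrated out.

1. **Prey selectivity** (`prey_selectivity`). For vessels stocked with a
   community of prey species, with or without the focal consumer:
   `logit(m) = a_s + b_s·S + z`, where `a_s` is the natural (control)
   logit-mortality of prey species `s`, `b_s` the shift caused by consumer
   presence, and `S ∈ {0,1}` the treatment indicator. Both are fixed
   effects. One shared `σ_obs²` governs every observation's `z`; a
   species-specific overdispersion variance would also be defensible, but
   the single-variance form matches the model as fitted and keeps the
   variance identifiable from 12 vessels.

2. **Predator identity** (`predator_effect`). For single-predator trials on
   the focal species: `logit(m) = a_0 + b_p + z` with a random predator
   effect `b_p ~ N(0, σ_pred²)`.

3. **Trait model** (`trait_full` / `trait_reduced`). Adds fixed trait
   effects on top of the identity model:

   `logit(m) = a0 + a1·x + a2·x² + a3·ambush + a4·suctorial + a5·pelagic + b_p + z`

   with `x = ln(w) − ln(w̄)` the centred log body mass. Reference levels
   are searching / chewing / benthic, so `a0` is the logit-mortality caused
   by a searching, chewing, benthic predator of mean mass. The *reduced*
   variant drops `a2` and `a5` structurally (their estimates are
   indistinguishable from zero); a reduced parameter object refuses to even
   carry those fields, so the two variants cannot be silently conflated.

**Centring base.** `w̄` is the arithmetic mean of the predator *species*
mean masses (13 values, unweighted by replicate counts) — "mean body mass
of all predators" read as the predator list, not the trial list. The
centring mass is configurable everywhere it enters (`mass_center`
arguments) for users who prefer replicate weighting.

**Trait coding.** The ambush, suctorial and pelagic indicators are coded
1 for those levels with searching/chewing/benthic as baseline. (The
model's original prose description contains an evident copy error defining
all three indicators in terms of foraging mode; the estimate-table row
labels fix the intended coding, which is what this package implements.)

## Priors

Every fixed-effect coefficient gets the diffuse `N(0, 10³)` used in the
original analysis. The original work does not state priors for the
variance components; this package puts half-normal(scale 10) priors on each
SD (`σ_obs`, `σ_pred`). Half-normals are proper and weakly informative on
the logit scale (an SD of 10 already saturates the link), and they avoid
the boundary pathologies of near-improper inverse-gamma precision priors.
Both hyper-parameters are exposed in `PriorConfig`.

## Sampling

An adaptive random-walk Metropolis-within-Gibbs sampler cycles over four
blocks: coefficients, predator effects, observation effects, SD components.

* Coefficients are updated one at a time (scalar random walks).
* Predator effects and observation effects touch disjoint likelihood
  slices, so all components of a block are proposed at once and accepted
  or rejected *independently*; each component therefore behaves as a
  scalar update, and the block shares one adaptive scale driven by its
  mean acceptance rate.
* SD components are updated on the log scale with the Jacobian correction,
  which removes boundary proposals at zero.

Proposal scales adapt by Robbins–Monro recursion (`log s += t^-0.6 ·
(acc − 0.44)`) toward the 0.44 scalar-optimal acceptance rate, during the
burn-in/adaptation phase only; every retained draw comes from a fixed
kernel, so detailed balance holds for the recorded chains. Chains
initialise at zero coefficients and unit SDs — well inside the
high-prior-mass region — and the sampler refuses to start from a
non-finite posterior.

**Chain protocol.** Burn-in runs first and is discarded; the sampling
phase of `n_steps` iterations is then thinned. The default configuration —
3 chains, 10⁶ sampling steps, thinning 100, burn-in 2·10³ — retains
exactly 10⁴ draws per chain, reproducing the original chain protocol.
`ChainConfig.test_scale()` (5·10⁴ steps, thinning 10) is the desk-scale
protocol used throughout the test suite and the recovery study; it is a
deliberately scaled-down configuration whose effective sample sizes
(roughly 10²–10³ for trait-model coefficients) are sufficient for the
moment and coverage checks performed at that scale. One master seed spawns
independent per-chain bit streams (`numpy` `SeedSequence.spawn`); a given
seed and configuration reproduce draws bit for bit.

**Degenerate data.** All-zero (or all-`n`) death patterns are not errors:
the proper priors keep the posterior integrable, and the fitted mortality
is pulled toward zero (or one) only as far as four or five trials warrant.
An empty table is also legal and returns draws from the prior — this is
used as a correctness check.

## Diagnostics

Split-chain Gelman–Rubin PSRF and Geyer initial-positive-sequence ESS are
implemented directly because the package fixes two conventions at the
degenerate corner: identical constant chains report PSRF = 1 (the
statistic is 0/0 there, and "no disagreement between chains" is the honest
reading), and a constant parameter reports ESS equal to the total draw
count together with a runtime warning. On well-behaved chains both agree
with `arviz` (cross-checked in the test suite).

## Verification strategy

Because no closed-form posterior exists, correctness rests on three
independent routes:

* **Quadrature oracle.** With random effects structurally fixed at zero
  and at most two free coefficients, the posterior is integrated by brute
  force on a fine grid; MCMC moments must match within Monte-Carlo error.
* **Prior recovery.** On an empty table the sampler must return the prior;
  coefficient draws are KS-tested against `N(0, 10³)`.
* **Parameter recovery.** Data simulated from the trait model at the
  published point estimates are refitted; bias and 95%-interval coverage
  of the mass slope are checked over 20 datasets.

## The synthetic-data generator

The simulators draw from the models' exact generative direction, using the
packaged designs:

* prey-choice: 6 consumer + 6 control vessels, each stocked with
  6 *Lymnaea*, 10 *Chironomus*, 10 *Cloeon*, 10 *Culex*, 10 *Asellus*
  and 30 *Daphnia*. Default truth: one heavily consumed species
  (*Chironomus*: baseline −4.6, consumer effect +7.5, i.e. ≈95%
  mortality when the consumer is present), the rest at a low natural
  mortality of `invlogit(−3.5) ≈ 3%`, and σ_obs = 0.5 — chosen to mirror
  the qualitative outcome of the original experiment (one strongly
  selected prey, mild control mortality) at realistic magnitudes.
* predation: 4–5 replicates per predator (54 trials over the 13 packaged
  predators), 10 focal individuals per trial, 4 predator-free controls.
  Default truth: the published reduced-model posterior means. Control
  natural mortality defaults to exactly 0 — the observed outcome — and is
  configurable for robustness checks.

What the simulator does **not** emulate: behavioural mechanism (encounter
rates, handling, satiation), within-trial death-time structure, any
predator-size × prey-size interaction beyond the fitted trait form, and
non-exchangeable vessel effects. Passing recovery tests therefore show
that *the estimation machinery is faithful to the assumed model*, not that
the model is faithful to live predators.

**Recovery design.** The original design (4–5 replicates per predator)
identifies the trait effects only weakly — credible intervals on the trait
contrasts span several logits, exactly as in the published table. The
default recovery study therefore inflates replicates fivefold (270
trials), which makes bias visible against the posterior spread while
keeping a 20-dataset study at desk scale. The original-scale design
remains available (`replicate_factor=1`) and is expected to produce wide,
honest intervals rather than tight recovery.

## Derived quantities

Trait-contrast fold changes are computed on the **probability** scale at
mean body mass with non-contrast traits at baseline:
`invlogit(a0 + c) / invlogit(a0)`. Evaluated at the published point
estimates this gives 8.1 (ambush vs searching, reduced-model means) and
6.6 (suctorial vs chewing, full-model means). Two routes exist: the
plug-in ratio at point estimates (the one that reproduces the printed
figures) and the posterior of the per-draw ratio (for uncertainty); by
Jensen's inequality their central values differ, and only the plug-in
route is expected to match the printed digits.

**Explained variance** is reported as a probability-scale R²:
`1 − Σ(p̂ − fit)² / Σ(p̂ − mean p̂)²`, with `p̂ = Y/n` and the fit the
inverse-logit of the *fixed-effects-only* linear predictor at plug-in
(mean or median) coefficients. Random effects are excluded deliberately:
it is the only reading under which a mass-only model can explain almost
nothing while the full trait model explains most of the between-trial
spread, as the original table reports. Since the original computation is
not documented, published explained-variance percentages should be treated
as refit-dependent rather than as exact contracts. The statistic is
undefined (NaN, with a warning) when all observed proportions are equal.

## Numerical notes

* Binomial log-likelihoods are computed as `y·η − n·log(1+e^η)` via
  `logaddexp`; no probability underflows for any finite `η`.
* Quantiles (95% CIs) use linear interpolation of the empirical CDF;
  MCSE uses non-overlapping batch means with `⌊√N⌋` batches (falling back
  to `sd/√N` below 4 draws).
* Non-positive variance components have prior density `−∞` (proposals
  there are rejected); the parameter containers can represent such states
  so that rejection, not exceptions, handles them.
* The mass-prediction curve warns (but still evaluates) outside the
  observed 2.74–528.43 mg predator mass range.

## Known limitations

* Componentwise Metropolis mixes slowly through the `a0`–`b_p` and
  `σ_pred`–`b_p` funnels; full-scale protocols (10⁶ steps) are advisable
  for publication-grade trait-model summaries, and PSRF/ESS should always
  be inspected.
* The supplementary raw data of the original study are not bundled; a
  column-name adapter (`SUPPLEMENTARY_COLUMN_MAP`) lets users feed them in
  when available. All packaged "data" beyond the two printed trait tables
  and the printed point estimates are synthetic.
* No model comparison (WAIC/LOO) is provided; the full→reduced step is the
  original drop-if-zero rule, not a selection procedure.
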