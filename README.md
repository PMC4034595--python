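# predmort

Bayesian analysis of invertebrate predation trials: who eats whom, how
much, and which predator traits drive it.

The package implements the hierarchical overdispersed-binomial models used
to quantify (1) prey mortality inflicted by a focal consumer (the water
bug *Sigara striata*) in multiple-choice feeding trials, (2) mortality of
that consumer caused by 13 invertebrate predators, and (3) the dependence
of that mortality on predator traits — body mass, foraging mode
(ambush/searching), feeding mode (chewing/suctorial) and microhabitat
(benthic/pelagic). It is aimed at community ecologists running vessel-scale
predation experiments who want fully Bayesian estimates with honest
uncertainty from small, overdispersed count data.

## The models

Deaths per trial are binomial with a logit-linear mortality and an
observation-level Gaussian overdispersion term:

```
Y_i ~ Bin(n_i, m_i)
prey choice:  logit(m_i) = a_s + b_s S_i + z_i                   z_i ~ N(0, σ²)
predator id:  logit(m_i) = a0 + b_p(i) + z_i                     b_p ~ N(0, σ₁²)
traits:       logit(m_i) = a0 + a1 x_i + a2 x_i² + a3 A_i
                           + a4 B_i + a5 C_i + b_p(i) + z_i      x_i = ln w_i − ln w̄
```

with `A`/`B`/`C` the ambush/suctorial/pelagic indicators and `w̄` the mean
predator body mass. The *reduced* trait model drops `a2` and `a5`.
Coefficients carry `N(0, 10³)` priors; SDs carry half-normal(10) priors.
Posteriors are sampled by adaptive Metropolis-within-Gibbs (3 chains ×
10⁶ steps, thinning 100, burn-in 2·10³ at the default protocol — 10⁴
retained draws per chain), with split-chain PSRF and ESS diagnostics, a
brute-force quadrature oracle for verification, and a full synthetic-data
generator for both experimental designs. See `docs/methods.md` for the
complete account.

## Worked example

Simulate a predation experiment at the packaged design (54 predator trials
+ 4 controls, generated at the published reduced-model estimates) and
refit it:

```python
import predmort as pm

table, truth = pm.simulate_predation_experiment(seed=1)
model = pm.TraitMortalityModel(variant="reduced", n_steps=50_000, thin=10,
                               burn_in=2_000, seed=0).fit(table)
print(pm.format_parameter_table(model.summary()))
```

```
model: trait_reduced
parameter                            mean (MCSE)                 median (95% CI)
intercept                          -4.49 (0.031)            -4.47 (-6.03, -3.10)
log_mass                            1.08 (0.006)               1.07 (0.62, 1.58)
ambush                              3.70 (0.037)               3.71 (1.98, 5.27)
suctorial                           2.96 (0.021)               2.91 (1.72, 4.46)
SD interspecific                    0.78 (0.015)               0.71 (0.08, 1.85)
SD intraspecific                    0.33 (0.016)               0.29 (0.00, 0.88)
Explained variance (%)                     86.0%                           86.2%
```

Each row is a posterior summary: the mass slope is recovered near its
generating value 1.0, and the ambush contrast's wide interval (1.98, 5.27)
contains its generating value 2.38 — 54 trials over 13 predators simply do
not pin trait contrasts down tightly. Derived quantities follow the same
pattern:

```python
model.mortality_ratio("ambush_vs_searching")                  # 28.1  (this dataset)
model.mortality_ratio("ambush_vs_searching", plug_in=False)   # median 27.7, 95% CI (5.8, 119.5)
```

The fold change by which an ambush predator of mean body mass out-kills a
searching one is 28.1 on this synthetic dataset, with a 95% interval
spanning an order of magnitude. Evaluated at the *published* point
estimates instead, the same machinery reproduces the printed contrasts:

```python
pm.mortality_ratio_at_mean_mass(pm.reference_params("reduced"), "ambush_vs_searching")
# 8.1
pm.mortality_ratio_at_mean_mass(pm.reference_params("full"), "suctorial_vs_chewing")
# 6.6
```

The same pipeline is scriptable from the shell:

```sh
predmort simulate --model trait_reduced --seed 1 --out trials.csv
predmort fit --data trials.csv --model trait_reduced --out samples.csv
predmort diagnose --samples samples.csv --out diag.json
predmort summarize --samples samples.csv --data trials.csv --out summary.json
predmort derive --contrast ambush_vs_searching --reference reduced   # prints 8.1
predmort reproduce --seed 1 --workdir out/                           # all stages
```

## Data

The only packaged data are the two printed trait tables (6 prey species,
13 predators) and the published point estimates of the trait model. All
trial-level data used in tests are generated by `predmort.simulate`. Users
with the original raw trial data can load them via
`read_trials(path, schema, column_map=...)`.
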