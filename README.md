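# propdiff

Estimators of the average proportion difference `Δ = E(Y|x=1) − E(Y|x=0)`
for responses on the open unit interval in a two-sample design, plus a
seeded Monte Carlo harness that compares them by bias, variance, type-1
error and power with Monte Carlo error estimates.

Four estimators are implemented:

| tag            | model                                                              |
|----------------|--------------------------------------------------------------------|
| `linear`       | OLS of y on the group indicator                                    |
| `beta_const`   | ML beta regression, logit mean link, single dispersion parameter   |
| `beta_vardisp` | ML beta regression, logit mean link, log-linked dispersion sub-model |
| `fraclogit`    | Bernoulli quasi-likelihood, logistic mean, robust sandwich variance |

The logit-mean models report `Δ̂ = expit(β̂₀+β̂₁) − expit(β̂₀)` with a
delta-method standard error; all models use a Wald test with the fixed
`|W| > 1.96` rule at α = 0.05.

Two built-in scenario registries drive the simulations: a 24-row grid of
two-group beta laws (mean/dispersion parameterization, null and shifted
rows) and a 4-row grid of discrete distributions on the ten points
{0.05, 0.15, …, 0.95}, each crossed with group sizes {25, 100, 250, 750}.

## Library use

```python
import propdiff as pdf

scenario = pdf.beta_scenario(6, 25)          # mu=0.25, phi0=5, phi1=10, n=25/group
data = pdf.draw_beta_two_sample(scenario, seed=1)
fit = pdf.fit_beta_const(data)
effect = pdf.effect_from_fit(fit)            # delta_hat, se, wald, reject

config = pdf.ExperimentConfig(scenario, reps=2000, seed=1)
summary = pdf.run_experiment(config)         # bias/variance/rejection + MC errors
```

## Command line

```bash
# one experiment: grid 1 row 1 at n=25 per group
propdiff --table 1 --row 1 --n 25 --reps 2000 --seed 7 --out results/

# every row of the discrete grid, all shipped group sizes
propdiff --table 2 --all --reps 500 --seed 1 --out results/
```

Flags: `--table {1,2}`, `--row K | --all`, `--n N` (repeatable),
`--models CSV`, `--reps INT`, `--seed INT`, `--alpha FLOAT`, `--out DIR`,
`--config FILE` (flat `key = value` defaults; flags win), `-v`.
Each run writes `summary_table<k>.csv` (one row per scenario × n, one
column block per model: bias, MC error of bias, empirical variance, MC
error of variance, rejection rate, MC error of rejection, mean
model-based variance, exclusion count) and a JSON run log with the seed,
package versions and per-experiment exclusion tallies. Identical
invocations produce byte-identical CSVs.

## Reproducibility

Replication `r` of an experiment uses an independent random substream
that depends only on `(seed, r)`, so any single replication can be
reproduced in isolation and replication-level parallelism cannot change
results. Non-converged fits (rare; the optimizer retries with jittered
starts) are excluded from summaries and counted per model.
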