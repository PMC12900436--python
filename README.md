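# crnlogit

Logistic-regression inference for stochastic mass-action reaction networks:
identify which species drive each reaction from jump-process trajectories,
and estimate kinetic/epidemic parameters when only part of the state is
observed.

## The idea

A chemical reaction network Σᵢ ν_ik Aᵢ → Σᵢ ν′_ik Aᵢ (k = 1…m), evolving as
a continuous-time Markov jump process with mass-action propensities
a_k(x) = κ_k Πᵢ x_i^(ν_ik) (0/1 multiplicities), has an embedded jump chain
whose conditional reaction-type law is *exactly* a multinomial logistic
regression in log molecular counts: taking a constant-rate (pure-birth)
reaction r as the reference,

```
log P(Y = k | X) / P(Y = r | X)  =  log(κ_k / κ_r) + Σᵢ ν_ik log Xᵢ .
```

So fitting a multinomial logit to (pre-jump counts, jump category) pairs
recovers each reaction's reactant set — including catalysts, which net
stoichiometry cannot reveal — as the significantly positive slopes
(one-sided P < 0.001, i.e. Z ≥ 3.09), and rate ratios as exponentiated
intercepts.

When only one coordinate is observed (an epidemic where just the infected
count I_t is recorded), the same logic gives a Bernoulli logistic model for
infection-vs-removal events with an *offset*: logit p_t = log(β/γ) + log s_t,
with the susceptible fraction s_t supplied by the deterministic SIR system
with demographic turnover.  A robust adaptive Metropolis (RAM) sampler
within a Gibbs loop estimates θ = (β, γ, ρ) and the effective population
size n, the latter redrawn each sweep from NegBinomial(n_I, τ_T) where n_I
is the observed infection count and τ_T the model-implied infection
probability by the horizon.

Details, numerical choices and limitations: [docs/methods.md](docs/methods.md).

## Worked example: identify a network from trajectories

```python
import crnlogit as cl

net = cl.builtin_model("tk", "symmetric")         # Togashi-Kaneko, kappa=200
ds = cl.simulate_ensemble(net, t_max=2000.0, n_traj=10, seed=1)
coefs, calls = cl.identify(ds)                    # reference: production of A2
print(calls.calls)
```

prints the reactant-call matrix (`+` = significant positive coefficient):

```
species  A1 A2
category
-A1       +
-A1+A2    +  +
-A2          +
+A1-A2    +  +
+A1
```

Reading it off: the two autocatalytic exchange reactions (`+A1-A2`,
`-A1+A2`) involve both species; each decay (`-A1`, `-A2`) involves its own
substrate; the zeroth-order production `+A1` has no reactants.  This is the
published identification pattern for the model, recovered from 10 seeded
trajectories.

The same pipeline runs from the shell:

```bash
crnlogit simulate --model tk --case symmetric --n-traj 10 --t-max 2000 \
    --seed 1 --out events.csv
crnlogit identify --events events.csv --alpha 0.001 --out coefs.csv
```

## Worked example: epidemic parameters from prevalence events

```python
import crnlogit as cl

truth = cl.OutbreakTruth(seed=7)           # beta=.36, gamma=.28, rho=1.2e-3, n=3e4
events, latent = cl.generate_outbreak(truth)
chain = cl.run_mcmc(events)                # 4000 iterations, first half burned
stats, r0 = cl.summarize(chain)
print(stats.round(4)); print(round(r0["r0_ratio_of_means"], 3))
```

```
           beta   gamma     rho           n
Min.     0.3355  0.2672  0.0008  25408.0000
1st Qu.  0.3573  0.2788  0.0011  28301.0000
Median   0.3632  0.2820  0.0013  29166.0000
Mean     0.3628  0.2823  0.0014  29348.6175
3rd Qu.  0.3681  0.2857  0.0015  30312.2500
Max.     0.3875  0.2993  0.0027  35489.0000
1.285
```

The sampler recovers the generator truth: recovery rate γ ≈ 0.282/day
(infectious period ≈ 3.6 days), basic reproduction number R₀ = β/γ ≈ 1.29,
initial infected fraction ρ ≈ 1.2·10⁻³, and an effective at-risk population
n ≈ 30,000 — the scale of a single metropolitan COVID-19 wave.

## Package layout

| module | contents |
|---|---|
| `crnlogit.crn_model` | network data model, YAML specs, propensities, built-in TK / heat-shock / SIR examples |
| `crnlogit.ssa_sim` | exact Gillespie simulation (numba kernel), ensembles, event-table CSV I/O |
| `crnlogit.structure_id` | categories, design matrix, multinomial-logit fit, significance calls, order/rate recovery |
| `crnlogit.epi_infer` | event series, SIR ODE offset, likelihood/priors, τ_T, RAM-within-Gibbs sampler, summaries |
| `crnlogit.synthetic_epi` | COVID-like synthetic outbreak generator and daily-prevalence helper |
| `crnlogit.cli` | `crnlogit simulate / identify / generate-epi / epifit` |
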