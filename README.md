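# revbandit

Simulation and analysis toolkit for **probabilistic reversal learning** in a
two-armed bandit: synthetic task generation, grid-based Bayesian observers that
infer reward probabilities together with the environment's volatility, a
logistic switch/stay choice policy with maximum-likelihood fitting and AIC
model comparison, and the standard behavioural switch analyses.

## The scientific problem

In a reversal bandit, an agent repeatedly chooses between two options whose
reward probabilities occasionally **reverse**: the better option abruptly
becomes the worse one. Adaptive behaviour requires estimating, trial by trial,
not only each option's reward probability *V* but also how likely the
environment is to have just changed. Two classic hypotheses about the internal
model are:

* **Model 2 (reversal model)** — the agent tracks a joint belief
  *p(V, H)* where *H* ∈ [0, 0.3] is the per-trial reversal probability.
  After each outcome the belief over *V* is updated with the Bernoulli
  likelihood (Bayes' rule) and then "leaks" towards a uniform distribution at
  rate *H*: with probability *H* a reversal has replaced the option's value by
  an arbitrary one.
* **Model 1 (drift model)** — the agent tracks *p(V, σ)* where σ is the
  standard deviation of a Gaussian random walk on *V*; values drift smoothly
  instead of reversing.

Both are implemented as exact discrete-grid Bayesian observers (101 value
points × 31 auxiliary points by default). From the beliefs the package derives
the trial-wise quantities used in behavioural and neural analyses: value point
estimates, 95% credible widths ("uncertainty"), the expected reversal rate
E[*H*], the expected value of switching, and Kullback–Leibler update
magnitudes.

Choices are modelled as a **switch/stay logistic policy**: the probability of
abandoning the previously chosen option is a logistic function of the
value-estimate difference, the uncertainty difference, and (Model 2 only) the
reversal estimate of the currently held option. Stimulation ("TUS")
conditions are modelled purely as perturbed policy presets.

## Worked example

```python
import revbandit as rb

# a correlated-task schedule: two anti-phased reward probabilities
sched = rb.gen_correlated_schedule(seed=7)
print("reversals at trials:", sched.reversal_trials)
print("corr(p_left, p_right) = %.3f" % sched.correlation())

# closed-loop simulation: Model 2 observer driving the sham policy
session = rb.simulate_session(sched, rb.SHAM_M2, seed=7, session_id="demo")
print("overall switch rate: %.3f" % session.switches().mean())
print(rb.consecutive_error_switch(session).to_string(index=False))

# refit the switch/stay policy by maximum likelihood
fit = rb.fit_policy(session, model="model2")
print(fit.summary())

comp = rb.compare_models(session)
print("delta AIC (model2 - model1): %.2f" % comp["delta_aic"])
```

Output:

```text
reversals at trials: [27, 60, 78, 99, 117, 132, 152]
corr(p_left, p_right) = -0.856
overall switch rate: 0.189
 run_length  n_events  n_switches  switch_rate
          1        35          16     0.457143
          2        10           7     0.700000
          3         2           2     1.000000
Switch/stay policy fit (model2, session demo)
  loglik = -19.6407   k = 4   AIC = 47.2813   converged = True
      bias =  1.3733 (se 6.0516)
   w_value = -9.6409 (se 2.0318)
     w_unc =  11.9488 (se 15.3715)
     w_rev =  18.6138 (se 35.9395)
delta AIC (model2 - model1): -29.98
```

The simulated animal switches rarely overall but escalates sharply with
consecutive non-rewards, and the reversal-rate policy (Model 2) describes its
choices far better than the drift policy — the signature of a correlated
(reversal-structured) environment.

## Command line

```bash
revbandit simulate --condition correlated --n-sessions 5 --seed 1 --out trials.tsv
revbandit observe trials.tsv --model model2 --out trace.tsv
revbandit fit trials.tsv --out fits.tsv
revbandit compare trials.tsv
revbandit analyze trials.tsv
revbandit recover --n-sessions 30 --seed 0
```

`simulate` also accepts a YAML config (`--config run.yml`) with keys
`condition`, `n_sessions`, `n_trials`, `seed`, `tus`, `model`, `policy`.

## Package layout

| module | contents |
| --- | --- |
| `revbandit.schedules` | reward-schedule generators, trial timing |
| `revbandit.session` | the behavioural record of one session |
| `revbandit.grids` / `observer` | hypothesis grids, Model 1/2 Bayesian observers |
| `revbandit.policy` | switch/stay policy, simulation, ML fitting, AIC |
| `revbandit.behaviour` | switch-rate and regression analyses, group inference |
| `revbandit.cohorts` / `recovery` | study-condition cohort builders, parameter recovery |
| `revbandit.io` / `cli` | TSV/YAML I/O and the `revbandit` command |

Methodological details, parameter provenance and numerical conventions are
documented in [`docs/methods.md`](docs/methods.md).
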