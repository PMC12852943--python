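# Methods

This document records the model definitions, parameter choices and numerical
conventions of `revbandit`, and the reasoning behind each.

## 1. Task generators

### Correlated schedules (`gen_correlated_schedule`)

The correlated task has two anti-phased latent states: in each state one
option's nominal reward probability is high (0.9) and the other's low (0.05).
Reversals between states occur at random trials; sessions are 170 trials with
1–7 reversals (drawn uniformly over the counts feasible at the session
length) and a minimum block length of 15 trials. Block lengths are a
uniformly random composition of the session length (stars-and-bars over the
slack above the minimum), so every admissible reversal placement is equally
likely.

Independent per-trial Gaussian jitter (sd 0.246, clipped to [0, 1]) is added
around the block levels. The jitter sd was **calibrated once**, before any
acceptance run, so that the population mean Pearson correlation between the
two options' probability series is ≈ −0.80; jittering whole blocks instead of
trials cannot reach that target (clipping saturates the correlation near
−0.86 and can produce degenerate constant series), which is why trial-level
jitter is used. Per-schedule correlations are negative for every schedule at
the default settings.

### Uncorrelated schedules (`gen_uncorrelated_schedule`)

Each option independently toggles between its high and low level with
per-trial probability 0.22, plus the same trial-level jitter. The change rate
was calibrated so that per-schedule correlations concentrate tightly around
zero (95% within ±0.2). Expected correlation is 0 by construction
(independent series).

### Trial timing (`sample_timing`)

Inter-trial intervals are uniform on [6.5, 7.5] s. Action–outcome delays are
drawn from a scaled Beta distribution on [0.103, 8.770] s whose two shape
parameters (α ≈ 10.72, β ≈ 17.52) are solved exactly from the Beta moment
equations to give mean 3.394 s and variance 0.605 s² — a bounded,
right-skewed delay with the targeted summary statistics.

## 2. Grid-based Bayesian observers

Beliefs are joint probability masses over a value grid (reward probability,
101 points on [0, 1], step 0.01) and an auxiliary grid (31 points on
[0, 0.3], step 0.01), initialised uniform. These sizes balance quantisation
error (≤ 0.005 on value point estimates) against cost; they are package
choices and can be overridden via `HypothesisGrid`.

Both observers share the Bernoulli outcome update
p(V, a | x) ∝ p(V, a) · V^x (1−V)^(1−x), applied only to the chosen option.
The trial transition is applied to **both** options every trial, because
volatility is a property of time, not of sampling.

* **Model 2 (reversal)**: the auxiliary variable is the per-trial reversal
  probability H. Transition per H-slice:
  new(v, h) = (1−h)·p(v, h) + h·p(h)/N_v — a mixture of the posterior and a
  uniform value distribution, weighted by the reversal probability. The
  uniform belief is a fixed point. Because H ≤ 0.3 on the grid, the reversal
  estimate E[H] can never exceed 0.3.
* **Model 1 (drift)**: the auxiliary variable is the drift sd σ. Transition
  per σ-slice: convolution of the value marginal with a discrete Gaussian
  kernel, truncated to [0, 1] and column-renormalised; σ = 0 is the
  identity.

Trial-wise derived quantities: value point estimates are posterior **modes**
under Model 2 (ties towards the smaller value) and posterior **means** under
Model 1; uncertainty is the central 95% credible width of the value marginal;
the reversal estimate is E[H]; the expected value of switching is the
unchosen option's marginal mean; update magnitudes are KL divergences across
the Bayes update — over the H marginal (Model 2) or the chosen option's value
marginal (Model 1).

**Credible-width convention.** The grid pmf is treated as density samples at
the nodes: the CDF is the cumulative trapezoid integral, normalised, inverted
by linear interpolation. Under this convention the uniform marginal has width
exactly 0.95 and a single-reward posterior (Beta(2,1)-shaped) has width
√0.975 − √0.025 ≈ 0.829, matching the analytic values. The alternative
convention (mass located at the points) misses the uniform anchor (0.9595)
and was rejected for that reason.

**Numerical safety.** Beliefs are renormalised with a floor of 1e−300 after
every step; a belief whose mass vanishes (possible only from a degenerate
prior) raises `NumericalDegeneracyError` rather than silently producing
NaNs. The observers are verified cellwise at 1e−12 against an independent
nested-loop implementation on a reduced grid, over every outcome sequence of
length 6.

## 3. Switch/stay choice policy

The choice likelihood is a **reconstruction** — the minimal switch/stay
policy consistent with the regressor set of the behavioural switch
regressions:

P(switch_t) = logistic(bias + w_value·Δprob + w_unc·Δunc + w_rev·E[H]_ref)

where all regressors are the observer's decision-time estimates referenced to
the previous trial's choice (the option held by staying), Δ denotes
reference-minus-alternative, and the reversal term exists only under Model 2
(k = 4 free weights vs k = 3 under Model 1). The first trial is excluded (no
previous choice). The same regressor convention is used for simulation,
likelihood evaluation and fitting, so the generating parameters are the
maximiser of the expected fitted likelihood.

Fitting: multi-start quasi-Newton ML (L-BFGS-B with the analytic gradient on
the numerically stable log-likelihood; 10 starts, the first at zero, the rest
uniform in [−5, 5]; loglik tolerance 1e−6). Standard errors come from the
inverse observed information. Model comparison uses AIC = 2k − 2·loglik;
ΔAIC = AIC(Model 2 policy) − AIC(Model 1 policy), negative favouring the
reversal model.

### Policy presets

The sham presets were calibrated once against the qualitative behavioural
pattern (overall switch rate ~14–19%, escalating to ~45% after one and ~70%
after two consecutive non-rewards in correlated sessions) and then frozen:

* `SHAM_M2` = (bias 0.5, w_value −10, w_unc 1.5, w_rev 20) — correlated
  sessions, Model 2 observer.
* `SHAM_M1` = (bias −1.5, w_value −6, w_unc 2) — uncorrelated sessions,
  Model 1 observer (no reversal estimate exists under Model 1).

Stimulation (TUS) conditions are modelled **only** as perturbed presets
(sign/zero patterns, magnitudes shared with sham):

* `dmpfc`: switching depends only on the chosen option's value estimate
  (value term = ref_prob − 0.5; w_unc = w_rev = 0);
* `hippocampus`: reversal influence abolished, uncertainty influence
  increased (w_rev = 0, w_unc = 3);
* `thalamus`: reversal influence sign-flipped, uncertainty influence
  increased (w_rev = −20, w_unc = 3).

### Synthetic study conditions

Correlated cohorts are generated by the Model 2 observer + `SHAM_M2`;
uncorrelated cohorts by the Model 1 observer + `SHAM_M1`. This choice *is*
the study design: it makes AIC model preference flip with the environment,
the pattern the model-comparison analysis is built to detect.

## 4. Behavioural statistics

* **Consecutive-error switch rates**: an event of run length r is a trial
  whose trailing r outcomes, for the same repeatedly chosen option, were all
  non-rewards (a reward or a switch resets the run); the response is whether
  the next choice switches. Runs of length 3 contribute one event at each
  length (nested counts).
* **Per-session switch regressions**: logistic regression of the switch
  indicator on per-session z-scored regressors — either the difference set
  (intercept, Δprob, Δunc, reversal estimate) or the per-option set
  (chosen/unchosen probability and uncertainty, reversal estimate). Fitted
  by hand-rolled IRLS (tolerance 1e−8, ≤ 100 iterations) because the
  algorithm is itself part of the specification; statsmodels `Logit` is the
  oracle in the tests. Coefficient norms above 25 flag (near-)perfect
  separation instead of raising.
* **Group inference** is two-stage: one-sample t and Wilcoxon tests of
  per-session coefficients against zero within groups; Welch t and
  Mann–Whitney tests between groups (≥ 3 sessions per group). The
  long-format coefficient table is exposed for external hierarchical
  refitting.
* **Session-type × error-count ANOVA**: two-way fixed-effects OLS ANOVA
  (statsmodels `anova_lm`, type II) on per-session switch rates in the
  condition × run-length layout.

## 5. Problem sizes and runtime

Defaults (170 trials, 101 × 31 grids, 10 optimiser starts) run a full
simulate–observe–fit cycle in well under 0.1 s per session on one CPU; the
complete acceptance suite (≈ 250 session simulations, observer runs and
fits) takes about half a minute.

## 6. Limitations

* **Weakly identified policy weights.** The uncertainty-difference regressor
  has small variance (sd ≈ 0.10) and correlates ≈ 0.79 with the reversal
  estimate — both spike after non-rewards — so the bias and uncertainty
  weights carry maximum-likelihood standard errors comparable to their own
  magnitudes even when 30 sessions (≈ 5,000 decisions) are pooled. Pooled
  recovery therefore pins down the value and reversal weights to within
  ~10% but cannot bound the bias/uncertainty weights below ~100% relative
  error in expectation; the corresponding acceptance test is kept and fails
  honestly (estimates remain within 2 SE of truth, i.e. the estimator is
  consistent and attains the Cramér–Rao bound; the bound itself is too
  loose at this scale).
* The choice likelihood is a reconstruction, not an estimate of any
  published likelihood; TUS conditions are behavioural caricatures
  (parameter patterns), not a physical stimulation model.
* Schedules jitter reward probabilities per trial; real schedules may hold
  probabilities constant within blocks with other sources of decorrelation.
* The two-stage group analysis treats per-session coefficients as exchange-
  able; subject identity is recorded but not modelled as a random effect
  (the long-format table supports doing so externally).
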