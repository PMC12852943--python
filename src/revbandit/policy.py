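"""Switch/stay choice policies over observer estimates, agent simulation,
maximum-likelihood policy fitting and AIC model comparison.

The policy is a Bernoulli-logistic switch/stay rule over the observer's
decision-time estimates, taken relative to the previous trial's choice (the
"reference" option the animal would repeat by staying):

    P(switch_t) = logistic(bias + w_value * dprob + w_unc * dunc
                           [+ w_rev * reversal_estimate])

where dprob/dunc are the reference-minus-alternative differences of the value
point estimates and 95% uncertainty widths, and the reversal estimate is E[H]
of the reference option's belief (Model 2 policies only). This likelihood is a
reconstruction: it is the minimal switch/stay policy consistent with the
regressor set of the behavioural switch analyses.

Transcranial ultrasound stimulation (TUS) conditions are modelled purely as
perturbed policy presets: parameter sign/zero patterns reproducing the
qualitative behavioural effects of stimulating each target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .grids import HypothesisGrid
from .observer import MODEL1, MODEL2, BayesianObserver, ObserverTrace
from .schedules import LEFT, RIGHT, RewardSchedule, deliver_outcome, sample_timing
from .session import Session

VALUE_DIFFERENCE = "difference"
VALUE_CHOSEN_ONLY = "chosen_only"


@dataclass(frozen=True)
class PolicyParams:
    """Weights of the logistic switch/stay policy.

    ``w_rev`` applies only to Model 2 policies. ``value_mode`` selects whether
    the value term is the reference-minus-alternative difference (default) or
    the reference option's value alone, centred at 0.5 (used by the dmPFC
    preset, whose switching depends only on the recently chosen option's
    estimated reward probability).
    """

    bias: float
    w_value: float
    w_unc: float = 0.0
    w_rev: float = 0.0
    value_mode: str = VALUE_DIFFERENCE

    def __post_init__(self) -> None:
        for name in ("bias", "w_value", "w_unc", "w_rev"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.value_mode not in (VALUE_DIFFERENCE, VALUE_CHOSEN_ONLY):
            raise ValueError(f"unknown value_mode: {self.value_mode!r}")


#: Sham (unperturbed) policy of the Model 2 agent; magnitudes calibrated once
#: so simulated correlated sessions reproduce the empirical switch-rate
#: pattern (low baseline switching, escalating after consecutive non-rewards).
SHAM_M2 = PolicyParams(bias=0.5, w_value=-10.0, w_unc=1.5, w_rev=20.0)
#: Sham policy of the Model 1 agent used in uncorrelated sessions (no
#: reversal-rate estimate is available under Model 1).
SHAM_M1 = PolicyParams(bias=-1.5, w_value=-6.0, w_unc=2.0, w_rev=0.0)

TUS_PRESETS = {
    "sham": SHAM_M2,
    # switching driven only by the recently chosen option's value estimate
    "dmpfc": replace(SHAM_M2, w_unc=0.0, w_rev=0.0, value_mode=VALUE_CHOSEN_ONLY),
    # reversal influence abolished; uncertainty influence increased
    "hippocampus": replace(SHAM_M2, w_rev=0.0, w_unc=3.0),
    # reversal influence sign-flipped; uncertainty influence increased
    "thalamus": replace(SHAM_M2, w_rev=-20.0, w_unc=3.0),
}


def tus_preset(target: str) -> PolicyParams:
    """Policy preset for a TUS condition: sham, dmpfc, hippocampus or thalamus."""
    try:
        return TUS_PRESETS[target]
    except KeyError:
        raise ValueError(
            f"unknown TUS target {target!r}; expected one of {sorted(TUS_PRESETS)}"
        ) from None


def switch_probability(estimates: dict, params: PolicyParams) -> float:
    """Probability of switching away from the reference (previous) choice.

    ``estimates`` must contain ``ref_prob``, ``alt_prob``, ``ref_unc``,
    ``alt_unc`` and, for policies with ``w_rev != 0``, ``ref_rev``.
    """
    if params.value_mode == VALUE_CHOSEN_ONLY:
        value_term = estimates["ref_prob"] - 0.5
    else:
        value_term = estimates["ref_prob"] - estimates["alt_prob"]
    z = (params.bias
         + params.w_value * value_term
         + params.w_unc * (estimates["ref_unc"] - estimates["alt_unc"]))
    if params.w_rev != 0.0:
        rev = estimates["ref_rev"]
        if not np.isfinite(rev):
            raise ValueError(
                "policy has a reversal weight but no finite reversal "
                "estimate is available (Model 1 beliefs carry no E[H])")
        z += params.w_rev * rev
    return float(expit(z))


def simulate_session(
    schedule: RewardSchedule,
    params: PolicyParams,
    model: str = MODEL2,
    grid: HypothesisGrid | None = None,
    seed=None,
    subject_id: str = "sim",
    session_id: str = "s0",
    tus: str = "none",
    with_timing: bool = True,
) -> Session:
    """Closed-loop simulation: observer estimates -> switch/stay -> outcome.

    The first trial has no previous choice; the side is drawn uniformly. On
    later trials the agent stays with or switches from its previous choice with
    the policy's switch probability evaluated on the current (pre-outcome)
    beliefs referenced to the previous choice.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    observer = BayesianObserver(model, grid)
    state = observer.init_state()
    n = schedule.n_trials
    choices = np.empty(n, dtype=object)
    outcomes = np.empty(n, dtype=int)
    prev: str | None = None
    for t in range(n):
        if prev is None:
            choice = LEFT if rng.integers(2) else RIGHT
        else:
            est = observer.side_estimates(state)
            ref, alt = (("left", "right") if prev == LEFT else ("right", "left"))
            p_switch = switch_probability(
                {
                    "ref_prob": est[f"{ref}_prob"],
                    "alt_prob": est[f"{alt}_prob"],
                    "ref_unc": est[f"{ref}_unc"],
                    "alt_unc": est[f"{alt}_unc"],
                    "ref_rev": est[f"{ref}_rev"],
                },
                params,
            )
            do_switch = rng.random() < p_switch
            choice = ({LEFT: RIGHT, RIGHT: LEFT}[prev] if do_switch else prev)
        outcome = deliver_outcome(schedule, t, choice, rng)
        choices[t] = choice
        outcomes[t] = outcome
        observer.update_with_outcome(state, choice, outcome)
        observer.transition_state(state)
        prev = choice
    timing = sample_timing(n, rng) if with_timing else []
    return Session(choices, outcomes, schedule=schedule, timing=timing,
                   subject_id=subject_id, session_id=session_id, tus=tus)


def _policy_design(trace: ObserverTrace, session: Session,
                   model: str) -> tuple[np.ndarray, np.ndarray]:
    """Raw regressor matrix (1, dprob, dunc[, rev]) and switch response.

    Regressors for trial t (t >= 2) are the decision-time estimates referenced
    to the previous trial's choice; the response is whether trial t's choice
    differs from it.
    """
    f = trace.frame
    prev_left = (session.choices[:-1] == LEFT)
    ref = np.where(prev_left, "left", "right")
    alt = np.where(prev_left, "right", "left")

    def col(kind: str, which: np.ndarray) -> np.ndarray:
        left = f[f"left_{kind}"].to_numpy()[1:]
        right = f[f"right_{kind}"].to_numpy()[1:]
        return np.where(which == "left", left, right)

    dprob = col("prob", ref) - col("prob", alt)
    dunc = col("unc", ref) - col("unc", alt)
    cols = [np.ones_like(dprob), dprob, dunc]
    if model == MODEL2:
        cols.append(col("rev", ref))
    x = np.column_stack(cols)
    y = session.switches().astype(float)
    return x, y


def session_loglik(session: Session, params: PolicyParams,
                   model: str = MODEL2, grid: HypothesisGrid | None = None,
                   trace: ObserverTrace | None = None) -> float:
    """Bernoulli log-likelihood (nats) of the observed switch/stay events.

    The first trial is excluded (no previous choice to stay with).
    """
    if session.n_trials < 2:
        raise ValueError("need at least 2 trials for switch/stay likelihood")
    if trace is None:
        trace = BayesianObserver(model, grid).run(session)
    x, y = _policy_design(trace, session, model)
    beta = _params_to_vector(params, model)
    return float(-_nll(beta, x, y))


def _params_to_vector(params: PolicyParams, model: str) -> np.ndarray:
    if params.value_mode != VALUE_DIFFERENCE:
        raise ValueError("likelihood evaluation expects a difference-form policy")
    vec = [params.bias, params.w_value, params.w_unc]
    if model == MODEL2:
        vec.append(params.w_rev)
    return np.asarray(vec)


def _nll(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    z = x @ beta
    # log(1 + exp(z)) - y*z, numerically stable
    return float(np.sum(np.logaddexp(0.0, z) - y * z))


def _nll_grad(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = expit(x @ beta)
    return x.T @ (p - y)


@dataclass
class PolicyFitResult:
    """Maximum-likelihood policy fit for one session.

    ``aic = 2k - 2*loglik`` with ``k`` the number of free weights (3 for
    Model 1 policies, 4 for Model 2 policies).
    """

    params: PolicyParams
    loglik: float
    k: int
    model: str
    converged: bool
    session_id: str = ""
    bse: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def summary(self) -> str:
        names = ["bias", "w_value", "w_unc"] + (["w_rev"] if self.k == 4 else [])
        vals = [self.params.bias, self.params.w_value, self.params.w_unc]
        if self.k == 4:
            vals.append(self.params.w_rev)
        lines = [
            f"Switch/stay policy fit ({self.model}, session {self.session_id})",
            f"  loglik = {self.loglik:.4f}   k = {self.k}   AIC = {self.aic:.4f}"
            f"   converged = {self.converged}",
        ]
        for i, (n, v) in enumerate(zip(names, vals)):
            se = f" (se {self.bse[i]:.4f})" if self.bse is not None else ""
            lines.append(f"  {n:>8s} = {v: .4f}{se}")
        return "\n".join(lines)


class SwitchPolicyModel:
    """Fits the logistic switch/stay policy to one session by ML.

    statsmodels-style: construct from data, call :meth:`fit` to obtain a
    :class:`PolicyFitResult`. The observer trace is computed once at
    construction (or supplied) and reused across optimiser starts.
    """

    MIN_TRIALS = 20

    def __init__(self, session: Session, model: str = MODEL2,
                 grid: HypothesisGrid | None = None,
                 trace: ObserverTrace | None = None):
        if model not in (MODEL1, MODEL2):
            raise ValueError(f"unknown model: {model!r}")
        if session.n_trials < self.MIN_TRIALS:
            raise ValueError(f"need >= {self.MIN_TRIALS} trials to fit a policy")
        if trace is None:
            trace = BayesianObserver(model, grid).run(session)
        elif trace.model_id != model:
            raise ValueError("supplied trace was computed under a different model")
        self.session = session
        self.model = model
        self.trace = trace
        self.x, self.y = _policy_design(trace, session, model)
        self.k = self.x.shape[1]

    def loglik(self, params: PolicyParams) -> float:
        return -_nll(_params_to_vector(params, self.model), self.x, self.y)

    def fit(self, starts: int = 10, seed: int = 0,
            tol: float = 1e-6) -> PolicyFitResult:
        """Multi-start quasi-Newton ML fit (starts uniform in [-5, 5])."""
        rng = np.random.default_rng(seed)
        best = None
        best_nll = np.inf
        any_converged = False
        for s in range(starts):
            beta0 = np.zeros(self.k) if s == 0 else rng.uniform(-5, 5, self.k)
            res = minimize(_nll, beta0, args=(self.x, self.y), jac=_nll_grad,
                           method="L-BFGS-B", options={"ftol": tol, "gtol": 1e-8})
            any_converged |= bool(res.success)
            if res.fun < best_nll:
                best_nll = res.fun
                best = res
        beta = best.x
        params = PolicyParams(
            bias=float(beta[0]), w_value=float(beta[1]), w_unc=float(beta[2]),
            w_rev=float(beta[3]) if self.k == 4 else 0.0,
        )
        # standard errors from the inverse observed information
        p = expit(self.x @ beta)
        w = p * (1.0 - p)
        info = self.x.T @ (self.x * w[:, None])
        try:
            var = np.diag(np.linalg.inv(info))
            bse = np.sqrt(var) if np.all(var > 0) else None
        except np.linalg.LinAlgError:
            bse = None
        return PolicyFitResult(
            params=params, loglik=float(-best_nll), k=self.k, model=self.model,
            converged=any_converged, session_id=self.session.session_id, bse=bse,
        )


def fit_policy(session: Session, model: str = MODEL2,
               grid: HypothesisGrid | None = None, starts: int = 10,
               seed: int = 0) -> PolicyFitResult:
    """Convenience wrapper: fit the switch/stay policy for one session."""
    return SwitchPolicyModel(session, model, grid).fit(starts=starts, seed=seed)


def compare_models(session: Session, grid2: HypothesisGrid | None = None,
                   grid1: HypothesisGrid | None = None, starts: int = 10,
                   seed: int = 0) -> dict:
    """AIC difference, Model 2 policy minus Model 1 policy (negative favours
    Model 2)."""
    fit2 = fit_policy(session, MODEL2, grid2, starts=starts, seed=seed)
    fit1 = fit_policy(session, MODEL1, grid1, starts=starts, seed=seed)
    return {
        "session_id": session.session_id,
        "aic_model2": fit2.aic,
        "aic_model1": fit1.aic,
        "delta_aic": fit2.aic - fit1.aic,
        "converged": fit2.converged and fit1.converged,
        "fit_model2": fit2,
        "fit_model1": fit1,
    }


def compare_models_table(sessions, **kwargs) -> pd.DataFrame:
    """Per-session AIC comparison table for a collection of sessions."""
    rows = []
    for s in sessions:
        c = compare_models(s, **kwargs)
        rows.append({k: c[k] for k in
                     ("session_id", "aic_model2", "aic_model1", "delta_aic",
                      "converged")})
    return pd.DataFrame(rows)
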