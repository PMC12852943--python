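"""Grid-based Bayesian observers for the reversal bandit.

Two observers are implemented, differing only in their trial-to-trial
transition function:

* **Model 2** (reversal model) tracks a joint belief p(V, H) over an option's
  reward probability V and a per-trial reversal probability H in [0, 0.3]. The
  transition mixes the value posterior with a uniform distribution, weighted by
  H ("uniform leak"): on each trial a reversal may have replaced the option's
  value by an arbitrary one.
* **Model 1** (drift model) tracks p(V, sigma) where sigma is the standard
  deviation of a Gaussian random-walk drift of the value; the transition
  convolves the value marginal with a Gaussian kernel per sigma hypothesis
  (truncated at [0, 1] and renormalised).

The outcome likelihood is Bernoulli in both models: p(x=1 | V) = V. Updates are
applied only to the chosen option's belief; the transition is applied to both
options every trial (volatility is a property of time, not of sampling).

Trial-wise estimates follow the conventions used throughout the behavioural and
neural analyses: value point estimates are posterior modes under Model 2 and
posterior means under Model 1; uncertainties are central 95% widths of the
value marginal; the reversal estimate is E[H]; update magnitudes are
Kullback-Leibler divergences across the outcome update (over the H marginal for
Model 2, over the chosen option's value marginal for Model 1).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import DRIFT_SD, REVERSAL_RATE, HypothesisGrid, default_grid
from .schedules import LEFT, RIGHT
from .session import Session

MODEL1 = "model1"
MODEL2 = "model2"

_FLOOR = 1e-300
_MASS_TOL = 1e-10


class NumericalDegeneracyError(RuntimeError):
    """Raised when a belief update annihilates all probability mass.

    This can only happen when the prior already concentrates all mass on
    hypotheses with zero likelihood (e.g. a point mass at V=1 observing a
    non-reward); it cannot occur from the uniform initialisation.
    """


class OptionBelief:
    """Normalised joint probability mass over (value, aux) for one option."""

    __slots__ = ("grid", "pmf")

    def __init__(self, grid: HypothesisGrid, pmf: np.ndarray, validate: bool = True):
        pmf = np.asarray(pmf, dtype=float)
        if pmf.shape != grid.shape:
            raise ValueError(f"pmf shape {pmf.shape} != grid shape {grid.shape}")
        if validate:
            if np.any(pmf < 0):
                raise ValueError("belief pmf has negative cells")
            if abs(pmf.sum() - 1.0) > _MASS_TOL:
                raise ValueError(f"belief mass {pmf.sum()} deviates from 1")
        self.grid = grid
        self.pmf = pmf

    @classmethod
    def uniform(cls, grid: HypothesisGrid) -> "OptionBelief":
        pmf = np.full(grid.shape, 1.0 / (grid.n_v * grid.n_aux))
        return cls(grid, pmf, validate=False)

    def value_marginal(self) -> np.ndarray:
        return self.pmf.sum(axis=1)

    def aux_marginal(self) -> np.ndarray:
        return self.pmf.sum(axis=0)

    def copy(self) -> "OptionBelief":
        return OptionBelief(self.grid, self.pmf.copy(), validate=False)


@dataclass
class BeliefState:
    """Beliefs of both options; they share one hypothesis grid."""

    model_id: str
    left: OptionBelief
    right: OptionBelief

    def __post_init__(self) -> None:
        if self.model_id not in (MODEL1, MODEL2):
            raise ValueError(f"unknown model_id: {self.model_id!r}")
        if self.left.grid != self.right.grid:
            raise ValueError("both options must share the same grid")

    def belief(self, side: str) -> OptionBelief:
        if side == LEFT:
            return self.left
        if side == RIGHT:
            return self.right
        raise ValueError(f"invalid side: {side!r}")

    def set_belief(self, side: str, belief: OptionBelief) -> None:
        if side == LEFT:
            self.left = belief
        elif side == RIGHT:
            self.right = belief
        else:
            raise ValueError(f"invalid side: {side!r}")


def _normalise(pmf: np.ndarray) -> np.ndarray:
    total = pmf.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise NumericalDegeneracyError(
            "belief mass vanished during an update; the prior placed all mass "
            "on hypotheses with zero likelihood (cannot occur from a uniform "
            "start on a grid including interior values)"
        )
    pmf = np.maximum(pmf, _FLOOR)
    return pmf / pmf.sum()


def outcome_likelihood(grid: HypothesisGrid, x: int) -> np.ndarray:
    """Bernoulli likelihood weight per value-grid point: V if x=1, 1-V if x=0."""
    if x not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {x!r}")
    return grid.v_values if x == 1 else 1.0 - grid.v_values


def bayes_update(belief: OptionBelief, x: int) -> OptionBelief:
    """Multiply by the outcome likelihood and renormalise."""
    w = outcome_likelihood(belief.grid, x)
    return OptionBelief(belief.grid, _normalise(belief.pmf * w[:, None]),
                        validate=False)


def transition_reversal(belief: OptionBelief) -> OptionBelief:
    """Model 2 trial transition: per-H mixture of the posterior and a uniform.

    For each reversal-rate hypothesis j, the next-trial prior over values is
    (1-j) times the value posterior conditional on H=j plus j times a uniform
    over values, each slice carrying the H marginal's weight; the joint is then
    renormalised.
    """
    if belief.grid.aux_kind != REVERSAL_RATE:
        raise ValueError("transition_reversal requires a reversal-rate grid")
    h = belief.grid.aux_values[None, :]
    p_h = belief.aux_marginal()[None, :]
    new = (1.0 - h) * belief.pmf + h * p_h / belief.grid.n_v
    return OptionBelief(belief.grid, _normalise(new), validate=False)


@functools.lru_cache(maxsize=8)
def drift_kernels(grid: HypothesisGrid) -> np.ndarray:
    """Per-sigma Gaussian transition matrices, shape (n_aux, n_v, n_v).

    Column k of kernel j is the (truncated, renormalised) distribution over
    next-trial values given current value v_k and drift sd sigma_j; sigma=0
    yields the identity.
    """
    v = grid.v_values
    kernels = np.empty((grid.n_aux, grid.n_v, grid.n_v))
    for j, sigma in enumerate(grid.aux_values):
        if sigma <= 0.0:
            kernels[j] = np.eye(grid.n_v)
            continue
        k = np.exp(-0.5 * ((v[:, None] - v[None, :]) / sigma) ** 2)
        kernels[j] = k / k.sum(axis=0, keepdims=True)
    kernels.setflags(write=False)
    return kernels


def transition_drift(belief: OptionBelief,
                     kernels: np.ndarray | None = None) -> OptionBelief:
    """Model 1 trial transition: Gaussian leak of the value marginal per sigma."""
    if belief.grid.aux_kind != DRIFT_SD:
        raise ValueError("transition_drift requires a drift-sd grid")
    if kernels is None:
        kernels = drift_kernels(belief.grid)
    # new[i, j] = sum_k kernels[j, i, k] * pmf[k, j]
    new = np.einsum("jik,kj->ij", kernels, belief.pmf)
    return OptionBelief(belief.grid, _normalise(new), validate=False)


def point_estimate(belief: OptionBelief, mode: str) -> float:
    """Point estimate of the value marginal: posterior mode or mean.

    Mode ties are broken towards the smallest grid value.
    """
    p = belief.value_marginal()
    if mode == "map":
        return float(belief.grid.v_values[int(np.argmax(p))])
    if mode == "mean":
        return float(np.dot(belief.grid.v_values, p) / p.sum())
    raise ValueError(f"unknown mode: {mode!r}")


def credible_width(belief: OptionBelief, lo: float = 0.025, hi: float = 0.975) -> float:
    """Central credible width (default 95%) of the value marginal.

    The grid pmf is treated as density samples at the nodes: the CDF is built
    by cumulative trapezoid integration, normalised, and inverted by linear
    interpolation. For a uniform marginal this yields exactly hi - lo.
    """
    p = belief.value_marginal()
    v = belief.grid.v_values
    increments = 0.5 * (p[1:] + p[:-1]) * np.diff(v)
    cdf = np.concatenate(([0.0], np.cumsum(increments)))
    cdf /= cdf[-1]
    q_lo, q_hi = np.interp([lo, hi], cdf, v)
    return float(q_hi - q_lo)


def reversal_probability(belief: OptionBelief) -> float:
    """Expected reversal rate E[H], marginalising over values (Model 2)."""
    if belief.grid.aux_kind != REVERSAL_RATE:
        raise ValueError("reversal_probability requires a Model 2 belief")
    return float(np.dot(belief.grid.aux_values, belief.aux_marginal()))


def reversal_ev(belief: OptionBelief) -> float:
    """Expected value of the option under its value marginal.

    Applied to the currently unchosen option's belief this is the expected
    reward probability of switching.
    """
    p = belief.value_marginal()
    return float(np.dot(belief.grid.v_values, p) / p.sum())


def kl_update(prior_marginal: np.ndarray, posterior_marginal: np.ndarray) -> float:
    """KL divergence (nats) of the posterior from the prior marginal.

    Both arguments must be normalised on the same grid; posterior support must
    be contained in the prior's.
    """
    q = np.asarray(prior_marginal, dtype=float)
    p = np.asarray(posterior_marginal, dtype=float)
    if p.shape != q.shape:
        raise ValueError("marginals must share a grid")
    for m in (p, q):
        if abs(m.sum() - 1.0) > 1e-8 or np.any(m < 0):
            raise ValueError("marginals must be normalised probability vectors")
    support = p > 0
    if np.any(support & (q <= 0)):
        raise ValueError("posterior has mass where the prior has none")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


@dataclass
class ObserverTrace:
    """Per-trial model-derived estimates aligned to a session.

    ``frame`` holds one row per trial (1-based ``trial`` column) with
    decision-time estimates per side and in chosen/unchosen coordinates, plus
    the KL update signals evaluated across the outcome update. ``final_state``
    is the belief state after the last trial's transition.
    """

    session_id: str
    model_id: str
    frame: pd.DataFrame
    final_state: BeliefState | None = None

    def __len__(self) -> int:
        return len(self.frame)

    TABLE_COLUMNS = [
        "trial", "choice", "outcome",
        "left_prob", "right_prob", "left_unc", "right_unc",
        "left_rev", "right_rev",
        "chosen_prob", "unchosen_prob", "chosen_unc", "unchosen_unc",
        "reversal_estimate", "reversal_ev", "reversal_dkl", "option_dkl",
    ]


class BayesianObserver:
    """Runs a grid-based Bayesian observer over sessions.

    Parameters
    ----------
    model : str
        ``"model2"`` (joint value x reversal-rate inference) or ``"model1"``
        (value x drift-sd inference).
    grid : HypothesisGrid, optional
        Defaults to the 101-point value grid crossed with a 31-point aux grid
        on [0, 0.3].
    """

    def __init__(self, model: str = MODEL2, grid: HypothesisGrid | None = None):
        if model not in (MODEL1, MODEL2):
            raise ValueError(f"unknown model: {model!r}")
        if grid is None:
            grid = default_grid(model)
        expected_kind = REVERSAL_RATE if model == MODEL2 else DRIFT_SD
        if grid.aux_kind != expected_kind:
            raise ValueError(f"{model} requires aux_kind={expected_kind!r}")
        self.model = model
        self.grid = grid
        self._kernels = drift_kernels(grid) if model == MODEL1 else None
        self._point_mode = "map" if model == MODEL2 else "mean"

    # -- state handling ----------------------------------------------------
    def init_state(self) -> BeliefState:
        return BeliefState(self.model, OptionBelief.uniform(self.grid),
                           OptionBelief.uniform(self.grid))

    def transition(self, belief: OptionBelief) -> OptionBelief:
        if self.model == MODEL2:
            return transition_reversal(belief)
        return transition_drift(belief, self._kernels)

    def transition_state(self, state: BeliefState) -> None:
        state.left = self.transition(state.left)
        state.right = self.transition(state.right)

    def value_point(self, belief: OptionBelief) -> float:
        return point_estimate(belief, self._point_mode)

    def side_estimates(self, state: BeliefState) -> dict[str, float]:
        """Decision-time estimates per side from the current (prior) beliefs."""
        out: dict[str, float] = {}
        for name, belief in (("left", state.left), ("right", state.right)):
            out[f"{name}_prob"] = self.value_point(belief)
            out[f"{name}_unc"] = credible_width(belief)
            out[f"{name}_rev"] = (reversal_probability(belief)
                                  if self.model == MODEL2 else np.nan)
        return out

    def update_with_outcome(self, state: BeliefState, choice: str,
                            outcome: int) -> float:
        """Apply the outcome update to the chosen option; return the KL signal.

        Model 2: KL over the chosen option's H marginal; Model 1: KL over the
        chosen option's value marginal (both across the Bayes update).
        """
        belief = state.belief(choice)
        pre = (belief.aux_marginal() if self.model == MODEL2
               else belief.value_marginal())
        updated = bayes_update(belief, outcome)
        post = (updated.aux_marginal() if self.model == MODEL2
                else updated.value_marginal())
        state.set_belief(choice, updated)
        return kl_update(pre, post)

    # -- full-session run --------------------------------------------------
    def run(self, session: Session) -> ObserverTrace:
        """Produce the per-trial estimate trace for a complete session.

        Per trial: (1) record decision-time estimates from the current priors,
        (2) update the chosen option's belief with the outcome and record the
        KL update signal, (3) apply the transition to both options to form the
        next trial's priors.
        """
        state = self.init_state()
        rows = []
        is_m2 = self.model == MODEL2
        for t in range(session.n_trials):
            choice = session.choices[t]
            outcome = int(session.outcomes[t])
            other = RIGHT if choice == LEFT else LEFT
            est = self.side_estimates(state)
            chosen_pref = "left" if choice == LEFT else "right"
            other_pref = "left" if other == LEFT else "right"
            row = {
                "trial": t + 1,
                "choice": choice,
                "outcome": outcome,
                **est,
                "chosen_prob": est[f"{chosen_pref}_prob"],
                "unchosen_prob": est[f"{other_pref}_prob"],
                "chosen_unc": est[f"{chosen_pref}_unc"],
                "unchosen_unc": est[f"{other_pref}_unc"],
                "reversal_estimate": est[f"{chosen_pref}_rev"],
                "reversal_ev": (reversal_ev(state.belief(other))
                                if is_m2 else np.nan),
            }
            dkl = self.update_with_outcome(state, choice, outcome)
            row["reversal_dkl"] = dkl if is_m2 else np.nan
            row["option_dkl"] = np.nan if is_m2 else dkl
            rows.append(row)
            self.transition_state(state)
        frame = pd.DataFrame(rows, columns=ObserverTrace.TABLE_COLUMNS)
        return ObserverTrace(session.session_id, self.model, frame, state)
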