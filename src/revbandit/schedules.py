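"""Reward-schedule generators and trial timing for the two-armed reversal bandit.

Two environments are emulated:

* **correlated** — two anti-phased latent states; in one state the left option
  carries the high reward probability and the right the low one, and vice versa.
  Reversals between states occur at random trials (1-7 per session), so the two
  options' per-trial reward probabilities are strongly negatively correlated
  (population mean Pearson r about -0.8 at the default settings).
* **uncorrelated** — each option alternates between its high and low level at
  its own, independent change points, so the expected correlation is zero.

Trial timing comprises a uniform inter-trial interval on [6.5, 7.5] s and an
action-outcome delay drawn from a moment-matched scaled Beta distribution on
[0.103, 8.770] s with mean 3.394 s and variance 0.605 s**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CORRELATED = "correlated"
UNCORRELATED = "uncorrelated"

LEFT = "L"
RIGHT = "R"
SIDES = (LEFT, RIGHT)

#: Action-outcome delay bounds (s) and target moments.
AOD_LO = 0.103
AOD_HI = 8.770
AOD_MEAN = 3.394
AOD_VAR = 0.605
ITI_LO = 6.5
ITI_HI = 7.5

# Beta(alpha, beta) on [AOD_LO, AOD_HI] matched to the target mean/variance.
_AOD_RANGE = AOD_HI - AOD_LO
_AOD_M = (AOD_MEAN - AOD_LO) / _AOD_RANGE
_AOD_V = AOD_VAR / _AOD_RANGE**2
_AOD_NU = _AOD_M * (1.0 - _AOD_M) / _AOD_V - 1.0
AOD_ALPHA = _AOD_M * _AOD_NU          # ~10.72
AOD_BETA = (1.0 - _AOD_M) * _AOD_NU   # ~17.52

#: Default generator settings (the study conditions).
DEFAULT_N_TRIALS = 170
DEFAULT_LEVEL_HIGH = 0.9
DEFAULT_LEVEL_LOW = 0.05
DEFAULT_MIN_BLOCK = 15
#: Per-trial Gaussian jitter sd around the block levels, calibrated so the
#: population mean Pearson r between the two options' correlated schedules is
#: about -0.8 (see docs/methods.md).
DEFAULT_LEVEL_JITTER = 0.246
#: Per-trial level change probability of each option in the uncorrelated task,
#: calibrated so per-schedule correlations concentrate near zero (95% of
#: schedules within +/-0.2; see docs/methods.md).
DEFAULT_CHANGE_RATE = 0.22
REVERSAL_RANGE = (1, 7)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class TrialTiming:
    """Timing of one trial: inter-trial interval and action-outcome delay (s)."""

    iti_s: float
    aod_s: float

    def __post_init__(self) -> None:
        if not (ITI_LO <= self.iti_s <= ITI_HI):
            raise ValueError(f"iti_s {self.iti_s} outside [{ITI_LO}, {ITI_HI}]")
        if not (AOD_LO <= self.aod_s <= AOD_HI):
            raise ValueError(f"aod_s {self.aod_s} outside [{AOD_LO}, {AOD_HI}]")


@dataclass
class RewardSchedule:
    """Ground-truth per-trial reward probabilities of both options.

    ``reversal_trials`` holds the 0-based trial indices at which the latent
    state switches (correlated condition) or at which either option's level
    changes (uncorrelated condition).
    """

    p_left: np.ndarray
    p_right: np.ndarray
    reversal_trials: list[int] = field(default_factory=list)
    condition: str = CORRELATED

    def __post_init__(self) -> None:
        self.p_left = np.asarray(self.p_left, dtype=float)
        self.p_right = np.asarray(self.p_right, dtype=float)
        if self.p_left.shape != self.p_right.shape or self.p_left.ndim != 1:
            raise ValueError("p_left and p_right must be 1d arrays of equal length")
        if self.n_trials < 1:
            raise ValueError("schedule must contain at least one trial")
        for p in (self.p_left, self.p_right):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("reward probabilities must lie in [0, 1]")
        rt = list(self.reversal_trials)
        if any(t2 <= t1 for t1, t2 in zip(rt, rt[1:])):
            raise ValueError("reversal_trials must be strictly increasing")
        if rt and (rt[0] < 1 or rt[-1] > self.n_trials - 1):
            raise ValueError("reversal_trials must lie in [1, n_trials-1]")
        if self.condition not in (CORRELATED, UNCORRELATED):
            raise ValueError(f"unknown condition: {self.condition!r}")
        # reversal metadata may be absent (e.g. schedules read back from a
        # trial table); when present on a correlated schedule it must be in
        # the generator's range
        if self.condition == CORRELATED and rt and not (
            REVERSAL_RANGE[0] <= len(rt) <= REVERSAL_RANGE[1]
        ):
            raise ValueError(
                f"correlated schedules must have {REVERSAL_RANGE[0]}-"
                f"{REVERSAL_RANGE[1]} reversals, got {len(rt)}"
            )
        self.reversal_trials = rt

    @property
    def n_trials(self) -> int:
        return self.p_left.size

    def p(self, trial: int, side: str) -> float:
        """Scheduled reward probability of ``side`` on ``trial`` (0-based)."""
        if not 0 <= trial < self.n_trials:
            raise IndexError(f"trial {trial} outside schedule of {self.n_trials}")
        if side == LEFT:
            return float(self.p_left[trial])
        if side == RIGHT:
            return float(self.p_right[trial])
        raise ValueError(f"invalid side: {side!r}")

    def correlation(self) -> float:
        """Pearson r between the two options' probability series."""
        return float(np.corrcoef(self.p_left, self.p_right)[0, 1])


def _block_lengths(n_trials: int, n_reversals: int, min_block: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniformly random block lengths >= min_block summing to n_trials."""
    k = n_reversals
    slack = n_trials - (k + 1) * min_block
    if slack < 0:
        raise ValueError(
            f"infeasible block constraint: {k} reversals with min_block="
            f"{min_block} need at least {(k + 1) * min_block} trials, got {n_trials}"
        )
    if k == 0:
        return np.array([n_trials])
    # uniform composition of `slack` into k+1 nonneg parts (stars and bars)
    cuts = np.sort(rng.choice(slack + k, size=k, replace=False))
    parts = np.diff(np.concatenate(([0], cuts + 1, [slack + k + 1]))) - 1
    return parts + min_block


def gen_correlated_schedule(
    n_trials: int = DEFAULT_N_TRIALS,
    n_reversals: int | None = None,
    level_high: float = DEFAULT_LEVEL_HIGH,
    level_low: float = DEFAULT_LEVEL_LOW,
    level_jitter: float = DEFAULT_LEVEL_JITTER,
    min_block: int = DEFAULT_MIN_BLOCK,
    seed=None,
) -> RewardSchedule:
    """Generate a correlated (two anti-phased latent states) schedule.

    When ``n_reversals`` is None, the reversal count is drawn uniformly from
    1-7. The nominal block levels receive independent per-trial Gaussian jitter
    (sd ``level_jitter``, clipped to [0, 1]), emulating the variability that
    keeps real schedules' correlation away from exactly -1; with the calibrated
    default sd the population mean Pearson r is about -0.8.
    """
    rng = _rng(seed)
    if not 0 <= level_low < level_high <= 1:
        raise ValueError("need 0 <= level_low < level_high <= 1")
    if n_reversals is None:
        # draw uniformly over the reversal counts feasible at this length
        hi = min(REVERSAL_RANGE[1], n_trials // min_block - 1)
        if hi < REVERSAL_RANGE[0]:
            raise ValueError(
                f"{n_trials} trials cannot hold {REVERSAL_RANGE[0]} reversal(s) "
                f"with min_block={min_block}")
        n_reversals = int(rng.integers(REVERSAL_RANGE[0], hi + 1))
    if not (REVERSAL_RANGE[0] <= n_reversals <= REVERSAL_RANGE[1]):
        raise ValueError(f"n_reversals must be in {REVERSAL_RANGE}")
    lengths = _block_lengths(n_trials, n_reversals, min_block, rng)
    left_high_first = bool(rng.integers(2))

    p_left = np.empty(n_trials)
    p_right = np.empty(n_trials)
    reversal_trials = [int(t) for t in np.cumsum(lengths[:-1])]
    start = 0
    for b, length in enumerate(lengths):
        left_is_high = left_high_first ^ (b % 2 == 1)
        p_left[start:start + length] = level_high if left_is_high else level_low
        p_right[start:start + length] = level_low if left_is_high else level_high
        start += length
    if level_jitter > 0:
        p_left = np.clip(p_left + rng.normal(0.0, level_jitter, n_trials), 0.0, 1.0)
        p_right = np.clip(p_right + rng.normal(0.0, level_jitter, n_trials), 0.0, 1.0)
    return RewardSchedule(p_left, p_right, reversal_trials, CORRELATED)


def gen_uncorrelated_schedule(
    n_trials: int = DEFAULT_N_TRIALS,
    change_rate: float = DEFAULT_CHANGE_RATE,
    level_high: float = DEFAULT_LEVEL_HIGH,
    level_low: float = DEFAULT_LEVEL_LOW,
    level_jitter: float = DEFAULT_LEVEL_JITTER,
    seed=None,
) -> RewardSchedule:
    """Generate an uncorrelated schedule: independent per-option level changes.

    Each option starts at a random high or low level and toggles between its
    levels with per-trial probability ``change_rate``; ``change_rate=0`` yields
    constant probabilities. The same per-trial Gaussian jitter as in the
    correlated generator is applied on top.
    """
    rng = _rng(seed)
    if not 0 <= change_rate < 1:
        raise ValueError("change_rate must lie in [0, 1)")

    change_trials: set[int] = set()

    def sample_series() -> np.ndarray:
        p = np.empty(n_trials)
        is_high = bool(rng.integers(2))
        for t in range(n_trials):
            if t > 0 and rng.random() < change_rate:
                is_high = not is_high
                change_trials.add(t)
            p[t] = level_high if is_high else level_low
        return p

    p_left = sample_series()
    p_right = sample_series()
    if level_jitter > 0:
        p_left = np.clip(p_left + rng.normal(0.0, level_jitter, n_trials), 0.0, 1.0)
        p_right = np.clip(p_right + rng.normal(0.0, level_jitter, n_trials), 0.0, 1.0)
    return RewardSchedule(p_left, p_right, sorted(change_trials), UNCORRELATED)


def sample_timing(n_trials: int, seed=None) -> list[TrialTiming]:
    """Sample per-trial timing: uniform ITI and moment-matched Beta AOD."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed)
    iti = rng.uniform(ITI_LO, ITI_HI, size=n_trials)
    aod = AOD_LO + _AOD_RANGE * rng.beta(AOD_ALPHA, AOD_BETA, size=n_trials)
    return [TrialTiming(float(i), float(a)) for i, a in zip(iti, aod)]


def deliver_outcome(schedule: RewardSchedule, trial: int, choice: str, rng) -> int:
    """Bernoulli reward (1/0) for choosing ``choice`` on ``trial``."""
    p = schedule.p(trial, choice)
    return int(_rng(rng).random() < p)
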