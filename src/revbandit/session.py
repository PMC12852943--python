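"""The behavioural record of one session: choices, outcomes and timing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedules import SIDES, RewardSchedule, TrialTiming

TUS_CONDITIONS = ("none", "sham", "dmpfc", "hippocampus", "thalamus")


@dataclass
class Session:
    """Choices and outcomes of one session, simulated or read from a table.

    ``choices`` are per-trial sides (``"L"``/``"R"``), ``outcomes`` binary
    rewards, both of length ``schedule.n_trials`` when a schedule is present.
    ``timing`` may be empty for behavioural records without timing fields.
    """

    choices: np.ndarray
    outcomes: np.ndarray
    schedule: RewardSchedule | None = None
    timing: list[TrialTiming] = field(default_factory=list)
    subject_id: str = "sim"
    session_id: str = "s0"
    tus: str = "none"

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=object)
        self.outcomes = np.asarray(self.outcomes, dtype=int)
        if self.choices.shape != self.outcomes.shape or self.choices.ndim != 1:
            raise ValueError("choices and outcomes must be 1d and equal length")
        bad = [s for s in np.unique(self.choices) if s not in SIDES]
        if bad:
            raise ValueError(f"invalid choice side(s): {bad}")
        if np.any((self.outcomes != 0) & (self.outcomes != 1)):
            raise ValueError("outcomes must be binary")
        if self.schedule is not None and self.schedule.n_trials != self.n_trials:
            raise ValueError("schedule length does not match number of trials")
        if self.timing and len(self.timing) != self.n_trials:
            raise ValueError("timing length does not match number of trials")
        if self.tus not in TUS_CONDITIONS:
            raise ValueError(f"unknown tus condition: {self.tus!r}")

    @property
    def n_trials(self) -> int:
        return self.choices.size

    @property
    def condition(self) -> str:
        return self.schedule.condition if self.schedule is not None else "unknown"

    def switches(self) -> np.ndarray:
        """Switch indicator for trials 1..n-1 (0-based): choice differs from previous."""
        return (self.choices[1:] != self.choices[:-1]).astype(int)
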