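"""Session and results I/O: trial tables (TSV), observer traces and YAML run
configuration.

The trial-table format has a frozen header so files round-trip exactly::

    session_id  condition  tus  trial  p_left  p_right  choice  outcome  iti_s  aod_s

One row per trial, ``trial`` 1-based; ``iti_s``/``aod_s`` may be empty for
records without timing. Floats are written with 10 significant digits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schedules import (CORRELATED, SIDES, UNCORRELATED, RewardSchedule,
                        TrialTiming)
from .session import TUS_CONDITIONS, Session

TRIAL_COLUMNS = ["session_id", "condition", "tus", "trial", "p_left",
                 "p_right", "choice", "outcome", "iti_s", "aod_s"]

_FLOAT_FMT = "%.10g"


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) \
        else _FLOAT_FMT % x


def write_sessions(sessions: list[Session], path) -> None:
    """Write one or more sessions to a trial-table TSV."""
    rows = []
    for s in sessions:
        if s.schedule is None:
            raise ValueError(
                f"session {s.session_id!r} has no schedule; trial tables "
                "require ground-truth probabilities")
        for t in range(s.n_trials):
            timing = s.timing[t] if s.timing else None
            rows.append({
                "session_id": s.session_id,
                "condition": s.schedule.condition,
                "tus": s.tus,
                "trial": t + 1,
                "p_left": _fmt(float(s.schedule.p_left[t])),
                "p_right": _fmt(float(s.schedule.p_right[t])),
                "choice": s.choices[t],
                "outcome": int(s.outcomes[t]),
                "iti_s": _fmt(timing.iti_s) if timing else "",
                "aod_s": _fmt(timing.aod_s) if timing else "",
            })
    frame = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def _row_err(path, i: int, msg: str) -> ValueError:
    return ValueError(f"{path}, data row {i + 1}: {msg}")


def read_sessions(path) -> list[Session]:
    """Read sessions back from a trial-table TSV, validating every row.

    Sessions are returned in file order; within a session, rows must be the
    contiguous 1..n trial sequence.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"session_id": str},
                        keep_default_na=False, na_values=[""])
    if list(frame.columns) != TRIAL_COLUMNS:
        raise ValueError(
            f"{path}: header {list(frame.columns)} does not match the "
            f"trial-table format {TRIAL_COLUMNS}")
    sessions: list[Session] = []
    for sid, sub in frame.groupby("session_id", sort=False):
        orig_idx = sub.index.to_numpy()
        sub = sub.reset_index(drop=True)
        base = int(orig_idx[0])
        n = len(sub)
        if list(sub["trial"]) != list(range(1, n + 1)):
            raise _row_err(path, base, f"session {sid!r} trials are not the "
                           "contiguous sequence 1..n")
        cond = sub["condition"].iloc[0]
        tus = str(sub["tus"].iloc[0])
        if cond not in (CORRELATED, UNCORRELATED):
            raise _row_err(path, base, f"unknown condition {cond!r}")
        if (sub["condition"] != cond).any() or (sub["tus"] != tus).any():
            raise _row_err(path, base, f"session {sid!r} mixes condition or "
                           "tus labels across rows")
        if tus not in TUS_CONDITIONS:
            raise _row_err(path, base, f"unknown tus condition {tus!r}")
        for i, row in sub.iterrows():
            j = int(orig_idx[i])
            if row["choice"] not in SIDES:
                raise _row_err(path, j, f"invalid choice {row['choice']!r}")
            if row["outcome"] not in (0, 1):
                raise _row_err(path, j, f"invalid outcome {row['outcome']!r}")
            for col in ("p_left", "p_right"):
                p = float(row[col])
                if not 0.0 <= p <= 1.0:
                    raise _row_err(path, j, f"{col}={p} outside [0, 1]")
        p_left = sub["p_left"].to_numpy(dtype=float)
        p_right = sub["p_right"].to_numpy(dtype=float)
        # reversal bookkeeping is not serialised; the reconstructed schedule
        # carries no reversal metadata
        schedule = RewardSchedule(p_left, p_right, [], cond)
        timing: list[TrialTiming] = []
        has_iti = sub["iti_s"].notna()
        has_aod = sub["aod_s"].notna()
        if has_iti.any() or has_aod.any():
            if not (has_iti.all() and has_aod.all()):
                raise _row_err(path, base, f"session {sid!r} has partial "
                               "timing columns; iti_s/aod_s must be all "
                               "present or all empty")
            try:
                timing = [TrialTiming(float(r["iti_s"]), float(r["aod_s"]))
                          for _, r in sub.iterrows()]
            except ValueError as e:
                raise _row_err(path, base, f"invalid timing: {e}") from e
        sessions.append(Session(
            choices=sub["choice"].to_numpy(dtype=object),
            outcomes=sub["outcome"].to_numpy(dtype=int),
            schedule=schedule, timing=timing,
            session_id=str(sid), tus=tus,
        ))
    return sessions


def write_trace_table(trace, path) -> None:
    """Write an observer trace's per-trial estimates to TSV (10 sig digits)."""
    trace.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_results(frame: pd.DataFrame, path) -> None:
    """Write an analysis results table to TSV with a deterministic layout."""
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration of a simulation run loaded from YAML."""

    condition: str = CORRELATED
    n_sessions: int = 35
    n_trials: int = 170
    seed: int = 0
    tus: str = "none"
    model: str = "model2"
    policy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in (CORRELATED, UNCORRELATED):
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.tus not in TUS_CONDITIONS:
            raise ValueError(f"unknown tus condition: {self.tus!r}")
        if self.model not in ("model1", "model2"):
            raise ValueError(f"unknown model: {self.model!r}")
        if not (isinstance(self.n_sessions, (int, np.integer))
                and self.n_sessions >= 1):
            raise ValueError("n_sessions must be a positive integer")
        if not (isinstance(self.n_trials, (int, np.integer))
                and self.n_trials >= 2):
            raise ValueError("n_trials must be an integer >= 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        allowed = {"bias", "w_value", "w_unc", "w_rev", "value_mode"}
        bad = set(self.policy) - allowed
        if bad:
            raise ValueError(f"unknown policy keys: {sorted(bad)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    data = {k: getattr(config, k) for k in RunConfig.__dataclass_fields__}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
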