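"""Cohort builders: batches of simulated sessions forming the study conditions.

The synthetic study mirrors the structure of the behavioural dataset the
package analyses:

* **correlated cohort** — sessions on correlated (anti-phased) schedules,
  generated by a Model 2 observer driving the sham logistic policy;
* **uncorrelated cohort** — sessions on uncorrelated schedules, generated by a
  Model 1 (drift) observer driving a three-weight sham policy (no
  reversal-rate regressor exists under Model 1);
* **TUS cohorts** — correlated-schedule sessions per stimulation condition
  (sham / dmPFC / hippocampus / anterior thalamus), each condition a perturbed
  policy preset, organised as subjects x sessions.

All randomness derives from a single seed via ``numpy`` child generators, so a
cohort is fully reproducible from ``(builder, seed)``.
"""

from __future__ import annotations

import numpy as np

from .observer import MODEL1, MODEL2
from .policy import SHAM_M1, SHAM_M2, PolicyParams, simulate_session, tus_preset
from .schedules import gen_correlated_schedule, gen_uncorrelated_schedule
from .session import Session

DEFAULT_N_SESSIONS = 35
DEFAULT_N_SUBJECTS = 3
DEFAULT_SESSIONS_PER_SUBJECT = 7


def _spawn(seed, n: int) -> list[np.random.Generator]:
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**63))
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def simulate_correlated_cohort(
    n_sessions: int = DEFAULT_N_SESSIONS,
    params: PolicyParams = SHAM_M2,
    n_trials: int | None = None,
    seed=0,
    tus: str = "none",
    subject_id: str = "simA",
    with_timing: bool = False,
) -> list[Session]:
    """Sessions on correlated schedules driven by the Model 2 sham policy."""
    sessions = []
    for i, rng in enumerate(_spawn(seed, n_sessions)):
        kwargs = {} if n_trials is None else {"n_trials": n_trials}
        sched = gen_correlated_schedule(seed=rng, **kwargs)
        sessions.append(simulate_session(
            sched, params, model=MODEL2, seed=rng,
            subject_id=subject_id, session_id=f"corr{i:03d}", tus=tus,
            with_timing=with_timing,
        ))
    return sessions


def simulate_uncorrelated_cohort(
    n_sessions: int = DEFAULT_N_SESSIONS,
    params: PolicyParams = SHAM_M1,
    n_trials: int | None = None,
    seed=0,
    subject_id: str = "simB",
    with_timing: bool = False,
) -> list[Session]:
    """Sessions on uncorrelated schedules driven by the Model 1 sham policy."""
    sessions = []
    for i, rng in enumerate(_spawn(seed, n_sessions)):
        kwargs = {} if n_trials is None else {"n_trials": n_trials}
        sched = gen_uncorrelated_schedule(seed=rng, **kwargs)
        sessions.append(simulate_session(
            sched, params, model=MODEL1, seed=rng,
            subject_id=subject_id, session_id=f"unc{i:03d}", tus="none",
            with_timing=with_timing,
        ))
    return sessions


def simulate_tus_cohort(
    condition: str,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    sessions_per_subject: int = DEFAULT_SESSIONS_PER_SUBJECT,
    n_trials: int | None = None,
    seed=0,
    with_timing: bool = False,
) -> list[Session]:
    """Correlated-schedule sessions under one TUS condition.

    ``condition`` is one of ``sham``, ``dmpfc``, ``hippocampus`` or
    ``thalamus``; sessions are labelled by synthetic subject.
    """
    params = tus_preset(condition)
    n_total = n_subjects * sessions_per_subject
    sessions = []
    for i, rng in enumerate(_spawn(seed, n_total)):
        subj = i // sessions_per_subject
        kwargs = {} if n_trials is None else {"n_trials": n_trials}
        sched = gen_correlated_schedule(seed=rng, **kwargs)
        sessions.append(simulate_session(
            sched, params, model=MODEL2, seed=rng,
            subject_id=f"subj{subj}",
            session_id=f"{condition}-s{subj}-{i % sessions_per_subject:02d}",
            tus=condition, with_timing=with_timing,
        ))
    return sessions


def simulate_study(
    conditions: tuple[str, ...] = ("sham", "dmpfc", "hippocampus", "thalamus"),
    n_subjects: int = DEFAULT_N_SUBJECTS,
    sessions_per_subject: int = DEFAULT_SESSIONS_PER_SUBJECT,
    seed=0,
) -> dict[str, list[Session]]:
    """All TUS cohorts keyed by condition, with disjoint randomness."""
    rngs = _spawn(seed, len(conditions))
    return {
        cond: simulate_tus_cohort(
            cond, n_subjects=n_subjects,
            sessions_per_subject=sessions_per_subject, seed=rng,
        )
        for cond, rng in zip(conditions, rngs)
    }
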