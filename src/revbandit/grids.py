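"""Hypothesis grids for the grid-based Bayesian observers.

Beliefs are joint probability masses over a value grid (reward probability of an
option, 101 points on [0, 1] by default) and an auxiliary grid that is either a
reversal-rate (hazard) grid or a drift-standard-deviation grid, both on [0, 0.3].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REVERSAL_RATE = "reversal_rate"
DRIFT_SD = "drift_sd"


@dataclass(frozen=True)
class HypothesisGrid:
    """Discrete hypothesis space for one option's belief.

    Parameters
    ----------
    v_values : 1d array
        Value (reward-probability) grid; strictly increasing, spanning [0, 1].
    aux_values : 1d array
        Auxiliary grid; strictly increasing, within [0, 0.3]. Interpreted as
        per-trial reversal probabilities (``aux_kind="reversal_rate"``, Model 2)
        or as drift standard deviations (``aux_kind="drift_sd"``, Model 1).
    aux_kind : str
        One of ``"reversal_rate"`` or ``"drift_sd"``.
    """

    v_values: np.ndarray
    aux_values: np.ndarray
    aux_kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.v_values, dtype=float)
        a = np.asarray(self.aux_values, dtype=float)
        object.__setattr__(self, "v_values", v)
        object.__setattr__(self, "aux_values", a)
        if self.aux_kind not in (REVERSAL_RATE, DRIFT_SD):
            raise ValueError(f"unknown aux_kind: {self.aux_kind!r}")
        if v.ndim != 1 or v.size < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("v_values must be 1d and strictly increasing")
        if a.ndim != 1 or a.size < 1 or (a.size > 1 and np.any(np.diff(a) <= 0)):
            raise ValueError("aux_values must be 1d and strictly increasing")
        if not (v[0] == 0.0 and v[-1] == 1.0):
            raise ValueError("value grid must span [0, 1] inclusive")
        if a[0] < 0.0 or a[-1] > 0.3 + 1e-12:
            raise ValueError("aux grid must lie within [0, 0.3]")

    @property
    def n_v(self) -> int:
        return self.v_values.size

    @property
    def n_aux(self) -> int:
        return self.aux_values.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_v, self.n_aux)

    def __eq__(self, other) -> bool:  # ndarray fields break dataclass eq
        if not isinstance(other, HypothesisGrid):
            return NotImplemented
        return (
            self.aux_kind == other.aux_kind
            and np.array_equal(self.v_values, other.v_values)
            and np.array_equal(self.aux_values, other.aux_values)
        )

    def __hash__(self) -> int:
        return hash((self.aux_kind, self.v_values.tobytes(), self.aux_values.tobytes()))


def default_grid(model: str, n_v: int = 101, n_aux: int = 31) -> HypothesisGrid:
    """Default grid for a model: value 0..1 step 0.01, aux 0..0.3 step 0.01.

    ``model`` is ``"model2"`` (reversal-rate hypotheses) or ``"model1"``
    (drift-sd hypotheses).
    """
    kind = {"model1": DRIFT_SD, "model2": REVERSAL_RATE}.get(model)
    if kind is None:
        raise ValueError(f"unknown model: {model!r}")
    return HypothesisGrid(
        v_values=np.linspace(0.0, 1.0, n_v),
        aux_values=np.linspace(0.0, 0.3, n_aux),
        aux_kind=kind,
    )
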