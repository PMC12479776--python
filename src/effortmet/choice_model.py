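"""Generative softmax model of incentivized effort choices.

Each trial offers a fixed low-incentive/low-effort option (E0) against a
high option with incentive level I in {1,2,3} and effort level E in
{1,2,3}.  The decision variable is the subjective value of accepting the
high option,

    SV = bias + kR*I            (gain trials; kP*I on loss trials)
             - (kEp + kFp*fatigue) * E   (physical trials)
             - (kEm - kLm*learning) * E  (mental trials)

mapped to a choice probability through the logistic function.  ``fatigue``
is the cumulative physical effort already exerted (normalized to the
session maximum) and ``learning`` the fraction of mental trials already
completed, so kFp inflates and kLm deflates the respective effort costs
over time.  Confidence is described as 2*|p - 0.5| and plays no role in
the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .task_design import SessionSchedule, TrialSpec, N_TRIALS

PARAM_NAMES = ("kR", "kP", "kEp", "kEm", "kFp", "kLm", "bias")
N_PARAMS = len(PARAM_NAMES)

# normalization constants of the dynamic regressors: half the 216 trials
# are mental; fatigue is scaled by the largest possible cumulative
# physical effort (108 trials at E3)
N_MENTAL_TRIALS = N_TRIALS // 2
MAX_CUMULATIVE_EFFORT = 3 * (N_TRIALS // 2)


@dataclass(frozen=True)
class BehavioralParameters:
    """The seven idiosyncratic sensitivities of the choice model."""

    kR: float
    kP: float
    kEp: float
    kEm: float
    kFp: float
    kLm: float
    bias: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")
        if np.any(vals[:6] < 0):
            raise ValueError("k-parameters must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "BehavioralParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} values")
        return cls(**dict(zip(PARAM_NAMES, values)))


@dataclass(frozen=True)
class TrialState:
    """Dynamic quantities carried across trials (both start at 0)."""

    fatigue: float = 0.0
    learning: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fatigue <= 1.0 and 0.0 <= self.learning <= 1.0):
            raise ValueError("fatigue and learning must lie in [0, 1]")


@dataclass
class ChoiceDataset:
    """Simulated or observed choices for one 216-trial session."""

    subject_id: str
    schedule: SessionSchedule
    frame: pd.DataFrame  # per-trial: schedule columns + sv, p_high, choice, ...
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.schedule):
            raise ValueError("record count must equal schedule trial count")


def subjective_value(
    params: BehavioralParameters, trial: TrialSpec, state: TrialState
) -> float:
    """Net value of the high option relative to the low one."""
    if trial.valence == "gain":
        benefit = params.kR * trial.incentive_level
    else:
        benefit = params.kP * trial.incentive_level  # value of the avoided loss
    if trial.effort_type == "physical":
        cost = (params.kEp + params.kFp * state.fatigue) * trial.effort_level
    else:
        cost = (params.kEm - params.kLm * state.learning) * trial.effort_level
    sv = params.bias + benefit - cost
    if not np.isfinite(sv):
        raise ValueError("subjective value is not finite")
    return float(sv)


def choice_probability(sv) -> float | np.ndarray:
    """Logistic probability of accepting the high-effort option."""
    return expit(sv)


def update_state(state: TrialState, trial: TrialSpec, choice: str) -> TrialState:
    """Advance fatigue/learning after a completed trial.

    Fatigue accrues only from chosen physical effort (the low option, E0,
    contributes nothing); learning advances with every completed mental
    trial regardless of the choice.
    """
    if trial.effort_type == "physical":
        exerted = trial.effort_level if choice == "high" else 0
        fatigue = min(state.fatigue + exerted / MAX_CUMULATIVE_EFFORT, 1.0)
        return replace(state, fatigue=fatigue)
    return replace(state, learning=min(state.learning + 1.0 / N_MENTAL_TRIALS, 1.0))


def simulate_choices(
    params: BehavioralParameters,
    schedule: SessionSchedule,
    seed: int,
    subject_id: str = "sim",
) -> ChoiceDataset:
    """Forward-simulate a session: roll the state, sample each choice."""
    rng = np.random.default_rng(seed)
    state = TrialState()
    frame = schedule.to_frame()
    svs = np.empty(len(frame))
    ps = np.empty(len(frame))
    choices: list[str] = []
    fatigue = np.empty(len(frame))
    learning = np.empty(len(frame))
    for i, trial in enumerate(schedule.trials):
        fatigue[i], learning[i] = state.fatigue, state.learning
        sv = subjective_value(params, trial, state)
        p = float(choice_probability(sv))
        choice = "high" if rng.random() < p else "low"
        svs[i], ps[i] = sv, p
        choices.append(choice)
        state = update_state(state, trial, choice)
    frame = frame.assign(
        sv=svs,
        p_high=ps,
        choice=choices,
        confidence_pred=2.0 * np.abs(ps - 0.5),
        fatigue=fatigue,
        learning=learning,
    )
    high = frame["choice"] == "high"
    summary = {
        "HME": float(high[frame["effort_type"] == "mental"].mean()),
        "HPE": float(high[frame["effort_type"] == "physical"].mean()),
    }
    return ChoiceDataset(subject_id=subject_id, schedule=schedule, frame=frame, summary=summary)


def summarize_behavior(ds: ChoiceDataset) -> pd.DataFrame:
    """High-effort choice rates overall and per design cell.

    Returns a tidy table of high-choice rates per
    (effort_type, valence, incentive_level, effort_level) cell — the grid
    behind the choice-rate heatmaps — with overall HME/HPE proportions
    attached in ``DataFrame.attrs``.
    """
    if len(ds.frame) == 0:
        raise ValueError("empty dataset")
    frame = ds.frame.assign(high=(ds.frame["choice"] == "high").astype(float))
    cells = (
        frame.groupby(["effort_type", "valence", "incentive_level", "effort_level"])
        .agg(n=("high", "size"), rate=("high", "mean"))
        .reset_index()
    )
    cells.attrs["HME"] = float(frame.loc[frame["effort_type"] == "mental", "high"].mean())
    cells.attrs["HPE"] = float(frame.loc[frame["effort_type"] == "physical", "high"].mean())
    return cells
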