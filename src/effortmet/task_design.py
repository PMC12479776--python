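"""Trial schedule for the incentivized effort-choice task.

A session consists of 216 binary choices between a fixed low-incentive /
low-effort option (E0, 0.5 CHF) and a varying high-incentive / high-effort
option, organised in 4 blocks of 54 trials.  Blocks alternate between
physical (handgrip) and mental (2-back) effort.  Within each block the
high option crosses valence (gain/loss) x incentive level (1-3) x effort
level (1-3), each of the 18 cells repeated 3 times, in pseudorandom order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

N_BLOCKS = 4
TRIALS_PER_BLOCK = 54
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK
EFFORT_TYPES = ("physical", "mental")
VALENCES = ("gain", "loss")
LEVELS = (1, 2, 3)
CELL_REPEATS = 3
LOW_INCENTIVE_CHF = 0.5
MAX_VALENCE_RUN = 4

SCHEDULE_COLUMNS = [
    "block",
    "trial_in_block",
    "effort_type",
    "valence",
    "incentive_level",
    "effort_level",
    "side",
]


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-subject calibration constants for the effort task.

    ``mvc`` is the maximal voluntary contraction force (arbitrary units),
    ``mncr`` the maximum number of correct 2-back responses in 10 s.
    ``indifference_incentives`` maps the three incentive levels to
    monetary amounts (CHF) obtained from the indifference-point
    calibration; the low option is fixed at 0.5 CHF.
    """

    mvc: float
    mncr: int
    indifference_incentives: tuple[float, float, float]
    low_incentive: float = LOW_INCENTIVE_CHF

    def __post_init__(self) -> None:
        if not self.mvc > 0:
            raise ValueError("mvc must be > 0")
        if self.mncr < 1:
            raise ValueError("mncr must be >= 1")
        a, b, c = self.indifference_incentives
        if not (a < b < c):
            raise ValueError("incentive levels must be strictly increasing")
        if self.low_incentive != LOW_INCENTIVE_CHF:
            raise ValueError("low-option incentive is fixed at 0.5 CHF")


@dataclass(frozen=True)
class TrialSpec:
    block_index: int
    effort_type: str
    valence: str
    incentive_level: int
    effort_level: int
    high_option_side: str

    def __post_init__(self) -> None:
        if self.block_index not in range(1, N_BLOCKS + 1):
            raise ValueError(f"block_index out of range: {self.block_index}")
        if self.effort_type not in EFFORT_TYPES:
            raise ValueError(f"unknown effort_type: {self.effort_type}")
        if self.valence not in VALENCES:
            raise ValueError(f"unknown valence: {self.valence}")
        if self.incentive_level not in LEVELS or self.effort_level not in LEVELS:
            raise ValueError("incentive/effort level must be in 1..3")
        if self.high_option_side not in ("left", "right"):
            raise ValueError(f"unknown side: {self.high_option_side}")


@dataclass
class SessionSchedule:
    trials: List[TrialSpec]
    block_order: tuple[str, ...]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        counter: dict[int, int] = {}
        for t in self.trials:
            counter[t.block_index] = counter.get(t.block_index, 0) + 1
            rows.append(
                {
                    "block": t.block_index,
                    "trial_in_block": counter[t.block_index],
                    "effort_type": t.effort_type,
                    "valence": t.valence,
                    "incentive_level": t.incentive_level,
                    "effort_level": t.effort_level,
                    "side": t.high_option_side,
                }
            )
        return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int | None = None) -> "SessionSchedule":
        trials = []
        for i, row in frame.iterrows():
            try:
                trials.append(
                    TrialSpec(
                        block_index=int(row["block"]),
                        effort_type=str(row["effort_type"]),
                        valence=str(row["valence"]),
                        incentive_level=int(row["incentive_level"]),
                        effort_level=int(row["effort_level"]),
                        high_option_side=str(row["side"]),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"malformed trial record at row {i}: {exc}") from exc
        block_order = tuple(
            frame.drop_duplicates("block").sort_values("block")["effort_type"]
        )
        return cls(trials=trials, block_order=block_order, seed=seed)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SessionSchedule":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "block_order": list(self.block_order),
            "trials": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _block_cells() -> list[tuple[str, int, int]]:
    return [
        (v, i, e)
        for v in VALENCES
        for i in LEVELS
        for e in LEVELS
        for _ in range(CELL_REPEATS)
    ]


def _max_run(values: Sequence[str]) -> int:
    best = run = 1
    for a, b in zip(values, values[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _shuffle_block(rng: np.random.Generator) -> list[tuple[str, int, int]]:
    cells = _block_cells()
    # reject orderings with long same-valence streaks to keep gains and
    # losses intermixed
    for _ in range(1000):
        order = rng.permutation(len(cells))
        shuffled = [cells[k] for k in order]
        if _max_run([c[0] for c in shuffled]) <= MAX_VALENCE_RUN:
            return shuffled
    raise RuntimeError("could not satisfy valence-run constraint")  # pragma: no cover


def generate_session(seed: int, start_type: str = "mental") -> SessionSchedule:
    """Generate the pseudorandom 216-trial schedule.

    ``start_type`` selects the block-counterbalance arm: sessions run
    either mental-physical-mental-physical or the reverse.  The same seed
    always yields the identical schedule.
    """
    if start_type not in EFFORT_TYPES:
        raise ValueError(f"start_type must be one of {EFFORT_TYPES}")
    rng = np.random.default_rng(seed)
    other = "physical" if start_type == "mental" else "mental"
    block_order = (start_type, other, start_type, other)
    trials: list[TrialSpec] = []
    for b, effort_type in enumerate(block_order, start=1):
        shuffled = _shuffle_block(rng)
        sides = np.array(["left"] * (TRIALS_PER_BLOCK // 2) + ["right"] * (TRIALS_PER_BLOCK // 2))
        rng.shuffle(sides)
        for (valence, inc, eff), side in zip(shuffled, sides):
            trials.append(
                TrialSpec(
                    block_index=b,
                    effort_type=effort_type,
                    valence=valence,
                    incentive_level=inc,
                    effort_level=eff,
                    high_option_side=str(side),
                )
            )
    return SessionSchedule(trials=trials, block_order=block_order, seed=seed)


def validate_schedule(schedule: SessionSchedule) -> list[str]:
    """Check a schedule against the design invariants.

    Returns a list of human-readable violation strings; empty when valid.
    """
    violations: list[str] = []
    frame = schedule.to_frame()

    if len(frame) != N_TRIALS:
        violations.append(f"trial_count: expected {N_TRIALS}, got {len(frame)}")

    blocks = sorted(frame["block"].unique())
    if blocks != list(range(1, N_BLOCKS + 1)):
        violations.append(f"block_count: expected blocks 1..{N_BLOCKS}, got {blocks}")

    for b, grp in frame.groupby("block"):
        if len(grp) != TRIALS_PER_BLOCK:
            violations.append(f"block_size: block {b} has {len(grp)} trials")
        types = grp["effort_type"].unique()
        if len(types) != 1:
            violations.append(f"block_homogeneity: block {b} mixes effort types")
        counts = grp.groupby(["valence", "incentive_level", "effort_level"]).size()
        if len(grp) == TRIALS_PER_BLOCK and (
            len(counts) != 18 or not (counts == CELL_REPEATS).all()
        ):
            violations.append(f"cell_balance: block {b} cells not balanced {CELL_REPEATS}x")

    order = [
        frame.loc[frame["block"] == b, "effort_type"].iloc[0]
        for b in blocks
        if (frame["block"] == b).any()
    ]
    if any(a == b for a, b in zip(order, order[1:])):
        violations.append(f"block_alternation: effort types do not alternate ({order})")
    if len(set(order)) < 2:
        violations.append("block_alternation: only one effort type present")

    n_left = int((frame["side"] == "left").sum())
    if len(frame) == N_TRIALS and n_left != N_TRIALS // 2:
        violations.append(f"side_balance: high option left {n_left} times, expected {N_TRIALS // 2}")

    return violations
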