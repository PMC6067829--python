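"""Mixed-gambles task design: the 13x13 gain-loss grid and randomized schedules.

The task presents mixed gambles offering a 50/50 chance of gaining or losing
money.  Gains run from +6 to +30 euros in steps of 2; losses from -3 to -15
euros in steps of 1 (stored here as positive magnitudes).  Every one of the
169 gain-loss pairs is shown exactly once per session, in randomized order,
split into three runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GAIN_LEVELS: tuple[int, ...] = tuple(range(6, 31, 2))
LOSS_LEVELS: tuple[int, ...] = tuple(range(3, 16, 1))
P_GAIN: float = 0.5
P_LOSS: float = 0.5
N_GAMBLES: int = len(GAIN_LEVELS) * len(LOSS_LEVELS)
N_RUNS: int = 3


@dataclass(frozen=True)
class Gamble:
    """One mixed gamble; ``loss`` is a positive magnitude."""

    gain: int
    loss: int
    p_gain: float = P_GAIN
    p_loss: float = P_LOSS

    def __post_init__(self) -> None:
        if self.gain not in GAIN_LEVELS:
            raise ValueError(f"gain {self.gain} not on the task grid {GAIN_LEVELS}")
        if self.loss not in LOSS_LEVELS:
            raise ValueError(f"loss {self.loss} not on the task grid {LOSS_LEVELS}")

    @property
    def expected_value(self) -> float:
        return self.p_gain * self.gain - self.p_loss * self.loss


@dataclass(frozen=True)
class TaskSchedule:
    """An ordered presentation of all 169 gambles, split into three runs."""

    trials: tuple[Gamble, ...]
    run_boundaries: tuple[int, ...]
    seed: int = field(default=0)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def run_index(self) -> np.ndarray:
        """0-based run label per trial."""
        idx = np.zeros(len(self.trials), dtype=int)
        for b in self.run_boundaries:
            idx[b:] += 1
        return idx

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a table with columns trial_index, run, gain, loss."""
        return pd.DataFrame(
            {
                "trial_index": np.arange(len(self.trials)),
                "run": self.run_index,
                "gain": [g.gain for g in self.trials],
                "loss": [g.loss for g in self.trials],
            }
        )


def build_gamble_grid() -> list[Gamble]:
    """Return all 169 distinct gain-loss pairs of the task (13 gains x 13 losses)."""
    return [Gamble(gain=g, loss=l) for g in GAIN_LEVELS for l in LOSS_LEVELS]


def build_schedule(seed: int) -> TaskSchedule:
    """Seeded random permutation of the full grid, split into runs of 57/56/56.

    The same seed always yields the same trial order.
    """
    rng = np.random.default_rng(seed)
    grid = build_gamble_grid()
    order = rng.permutation(len(grid))
    trials = tuple(grid[i] for i in order)
    # closest-to-equal split of 169 into three runs, in schedule order
    base, extra = divmod(len(grid), N_RUNS)
    sizes = [base + (1 if i < extra else 0) for i in range(N_RUNS)]
    boundaries = tuple(np.cumsum(sizes)[:-1].tolist())
    return TaskSchedule(trials=trials, run_boundaries=boundaries, seed=seed)
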