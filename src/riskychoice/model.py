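"""Prospect-theory valuation and the biased-softmax choice rule.

A mixed gamble with 50/50 outcome probabilities has subjective utility

    SUG = p_gain * gain - p_loss * loss * lambda

with a linear value function and no probability weighting.  The probability
of accepting the gamble is a logistic function of the utility,

    p(accept) = 1 / (1 + exp(-(mu * SUG + c)))

where mu is the inverse temperature (choice consistency) and c a
value-independent gambling bias: c > 0 pushes toward accepting any gamble,
c < 0 toward rejecting, regardless of its value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import TaskSchedule

# box constraints used by the hierarchical fit
LAM_BOUNDS = (0.0, 10.0)
MU_BOUNDS = (0.0, 10.0)
C_BOUNDS = (-10.0, 10.0)

PARAM_NAMES = ("lam", "mu", "c")

#: probability clamp applied before taking logs, for saturated parameters
P_CLIP = 1e-12

TRIAL_COLUMNS = ["subject_id", "group", "session", "trial_index", "gain", "loss", "accepted"]


@dataclass(frozen=True)
class ParameterSet:
    """Model parameters (lam, mu, c) for one subject-session.

    ``model_variant`` is "full" (three free parameters) or "no_bias"
    (c fixed at zero).
    """

    lam: float
    mu: float
    c: float = 0.0
    model_variant: str = "full"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("loss aversion lam must be nonnegative")
        if self.model_variant not in ("full", "no_bias"):
            raise ValueError(f"unknown model variant {self.model_variant!r}")
        if self.model_variant == "no_bias" and self.c != 0.0:
            raise ValueError("no_bias variant requires c == 0")

    def as_array(self) -> np.ndarray:
        if self.model_variant == "no_bias":
            return np.array([self.lam, self.mu])
        return np.array([self.lam, self.mu, self.c])


def subjective_utility(gain, loss, lam, p_gain: float = 0.5, p_loss: float = 0.5):
    """Subjective utility of a gamble: ``p_gain*gain - p_loss*loss*lam``.

    ``loss`` is a positive magnitude.  Accepts scalars or arrays.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("loss aversion lam must be nonnegative")
    return p_gain * np.asarray(gain, dtype=float) - p_loss * np.asarray(loss, dtype=float) * lam


def acceptance_probability(sug, mu, c=0.0):
    """Probability of accepting a gamble: logistic(mu*SUG + c)."""
    return expit(np.asarray(mu, dtype=float) * np.asarray(sug, dtype=float) + c)


def _logit(gain, loss, lam, mu, c):
    """Linear predictor mu*SUG + c; no parameter validation (internal)."""
    return mu * (0.5 * np.asarray(gain, float) - 0.5 * np.asarray(loss, float) * lam) + c


def log_likelihood(data: pd.DataFrame, params: ParameterSet) -> float:
    """Bernoulli log-likelihood of accept/reject choices for one subject-session.

    ``data`` needs columns gain, loss, accepted.  Probabilities are clamped
    to [P_CLIP, 1-P_CLIP] before the log so saturated parameters stay finite.
    """
    if len(data) == 0:
        raise ValueError("empty choice dataset")
    p = acceptance_probability(
        subjective_utility(data["gain"].to_numpy(), data["loss"].to_numpy(), params.lam),
        params.mu,
        params.c,
    )
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    y = data["accepted"].to_numpy().astype(bool)
    return float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


def simulate_choices(
    schedule: TaskSchedule,
    params: ParameterSet,
    seed: int,
    subject_id: str = "sim",
    group: str = "HC",
    session: str = "single",
) -> pd.DataFrame:
    """Forward-simulate one session: a Bernoulli draw per trial at the model's p(accept)."""
    rng = np.random.default_rng(seed)
    frame = schedule.to_frame()
    p = acceptance_probability(
        subjective_utility(frame["gain"].to_numpy(), frame["loss"].to_numpy(), params.lam),
        params.mu,
        params.c,
    )
    frame.insert(0, "subject_id", subject_id)
    frame.insert(1, "group", group)
    frame.insert(2, "session", session)
    frame["accepted"] = (rng.random(len(frame)) < p).astype(int)
    return frame[TRIAL_COLUMNS + ["run"]]


def read_choices(path) -> pd.DataFrame:
    """Read a trial-level choice table (CSV) and check the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice table missing columns: {missing}")
    return df


def write_choices(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
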