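"""Synthetic study cohorts for the mixed-gambles drug-withdrawal design.

Emulates the study structure end to end: healthy controls tested once, two
Parkinson patient groups (nondepressed, and with a depression history) each
tested ON and OFF dopaminergic medication, 169 gambles per session.  True
per-subject parameters are drawn from truncated normals within the model
bounds; choices are forward-simulated from the choice model; BDI depression
scores follow the group distributions; and two causal hooks are built in:

* a drug effect on the gambling bias c in nondepressed patients
  (c_ON = c_OFF + shift), and
* a coupling of the drug effect on loss aversion to OFF-state depression
  severity, d_lam = slope * (BDI_OFF - group mean BDI) + noise, which makes
  corr(BDI_OFF, lam_ON - lam_OFF) negative when the slope is negative.

Ground-truth parameters are returned so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import model, task

GROUPS = ("HC", "PD_nondep", "PD_dep_hist")


@dataclass
class CohortConfig:
    """Generative settings; defaults emulate the study's group structure."""

    n_hc: int = 23
    n_ndpd: int = 22
    n_dpd: int = 21
    # group-level parameter distributions (truncated/clipped to model bounds)
    lam_mean: float = 1.3
    lam_sd: float = 0.6
    mu_mean: float = 1.0
    mu_sd: float = 0.4
    c_off_mean: dict = field(
        default_factory=lambda: {"HC": -0.65, "PD_nondep": -2.0, "PD_dep_hist": -1.7}
    )
    c_sd: float = 1.5
    # drug effects on the gambling bias (OFF -> ON shift of c)
    drug_effect_c_ndpd: float = 1.7
    drug_effect_c_dpd: float = 0.4
    c_session_noise_sd: float = 0.5
    # coupling of the lambda drug effect to OFF-state depression severity
    lambda_bdi_slope: float = -0.04
    lambda_effect_noise_sd: float = 0.40
    # BDI distributions per group (mean, sd), OFF state
    bdi_mean: dict = field(
        default_factory=lambda: {"HC": 3.1, "PD_nondep": 4.0, "PD_dep_hist": 9.9}
    )
    bdi_sd: dict = field(
        default_factory=lambda: {"HC": 2.1, "PD_nondep": 2.3, "PD_dep_hist": 6.1}
    )
    # drug-induced BDI improvement, ON relative to OFF: group mean, a slope
    # on OFF-state severity (patients with higher OFF scores improve more),
    # and residual noise
    bdi_improvement_mean: dict = field(
        default_factory=lambda: {"PD_nondep": 0.0, "PD_dep_hist": 2.0}
    )
    bdi_improvement_bdi_slope: float = 0.5
    bdi_improvement_sd: dict = field(
        default_factory=lambda: {"PD_nondep": 2.0, "PD_dep_hist": 2.5}
    )
    # levodopa-equivalent dose and impulse-control-disorder rates
    led_mean: float = 590.0
    led_sd: float = 260.0
    icd_rate: dict = field(default_factory=lambda: {"PD_nondep": 1 / 22, "PD_dep_hist": 4 / 21})
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_hc, self.n_ndpd, self.n_dpd) < 1:
            raise ValueError("group counts must be >= 1")
        sds = [self.lam_sd, self.mu_sd, self.c_sd, self.c_session_noise_sd,
               self.lambda_effect_noise_sd, self.led_sd,
               *self.bdi_sd.values(), *self.bdi_improvement_sd.values()]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.broadcast_to(np.clip(mean, lo, hi), () if size is None else (size,)).copy()
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns ``(trials, clinical, truth)``: the trial-level choice table, the
    per-subject clinical table (BDI per session, LED, ICD flag, session
    order), and the ground-truth parameter table (one row per
    subject-session with the generating lam, mu, c).
    """
    config = config or CohortConfig()
    if seed is not None:
        config = CohortConfig(**{**config.to_dict(), "seed": seed})
    config.validate()
    root = np.random.default_rng(np.random.SeedSequence(config.seed))

    subjects = (
        [("HC", f"HC{i:02d}") for i in range(config.n_hc)]
        + [("PD_nondep", f"ND{i:02d}") for i in range(config.n_ndpd)]
        + [("PD_dep_hist", f"DP{i:02d}") for i in range(config.n_dpd)]
    )
    c_shift = {"PD_nondep": config.drug_effect_c_ndpd, "PD_dep_hist": config.drug_effect_c_dpd}

    trial_frames, clinical_rows, truth_rows = [], [], []
    order_counter = {g: 0 for g in GROUPS}
    for group, sid in subjects:
        lam_off = float(_truncnorm(root, config.lam_mean, config.lam_sd, *model.LAM_BOUNDS))
        mu = float(_truncnorm(root, config.mu_mean, config.mu_sd, *model.MU_BOUNDS))
        c_off = float(np.clip(root.normal(config.c_off_mean[group], config.c_sd), *model.C_BOUNDS))
        bdi_off = int(round(_truncnorm(root, config.bdi_mean[group], config.bdi_sd[group], 0, 63)))

        if group == "HC":
            sessions = {"single": (lam_off, mu, c_off)}
            bdi_on = np.nan
            led = np.nan
            icd = False
            order = ""
        else:
            d_lam = (
                config.lambda_bdi_slope * (bdi_off - config.bdi_mean[group])
                + root.normal(0.0, config.lambda_effect_noise_sd)
            )
            lam_on = float(np.clip(lam_off + d_lam, *model.LAM_BOUNDS))
            c_on = float(
                np.clip(
                    c_off + c_shift[group] + root.normal(0.0, config.c_session_noise_sd),
                    *model.C_BOUNDS,
                )
            )
            sessions = {"OFF": (lam_off, mu, c_off), "ON": (lam_on, mu, c_on)}
            improvement = (
                config.bdi_improvement_mean[group]
                + config.bdi_improvement_bdi_slope * (bdi_off - config.bdi_mean[group])
                + root.normal(0.0, config.bdi_improvement_sd[group])
            )
            bdi_on = int(max(0, round(bdi_off - improvement)))
            led = float(max(0.0, root.normal(config.led_mean, config.led_sd)))
            icd = bool(root.random() < config.icd_rate[group])
            # counterbalanced session order, alternating within each group
            order = "ON_first" if order_counter[group] % 2 == 0 else "OFF_first"
            order_counter[group] += 1

        for session, (lam, m_, c) in sessions.items():
            sched_seed = int(root.integers(2**31))
            choice_seed = int(root.integers(2**31))
            sched = task.build_schedule(sched_seed)
            params = model.ParameterSet(lam=lam, mu=m_, c=c)
            trial_frames.append(
                model.simulate_choices(
                    sched, params, choice_seed, subject_id=sid, group=group, session=session
                )
            )
            truth_rows.append(
                {"subject_id": sid, "group": group, "session": session,
                 "lam": lam, "mu": m_, "c": c}
            )
        clinical_rows.append(
            {"subject_id": sid, "group": group, "bdi_off": bdi_off, "bdi_on": bdi_on,
             "led": led, "icd_flag": icd, "session_order": order}
        )

    trials = pd.concat(trial_frames, ignore_index=True)
    return trials, pd.DataFrame(clinical_rows), pd.DataFrame(truth_rows)


def generate_contaminant(
    kind: str, schedule: task.TaskSchedule | None = None, seed: int = 0,
    strength: float = 10.0, subject_id: str | None = None,
) -> pd.DataFrame:
    """Simulate a non-utility-maximizing session.

    "inverted": choices driven by a negative effective inverse temperature
    (accepts more as losses grow and gains shrink).  "random": p = 0.5 on
    every trial.
    """
    if schedule is None:
        schedule = task.build_schedule(seed)
    rng = np.random.default_rng(seed)
    frame = schedule.to_frame()
    if kind == "inverted":
        sug = model.subjective_utility(frame["gain"].to_numpy(), frame["loss"].to_numpy(), 1.0)
        p = model.acceptance_probability(sug, -abs(strength), 0.0)
        sid = subject_id or "CONTAM_INV"
    elif kind == "random":
        p = np.full(len(frame), 0.5)
        sid = subject_id or "CONTAM_RND"
    else:
        raise ValueError(f"unknown contaminant kind {kind!r}")
    frame.insert(0, "subject_id", sid)
    frame.insert(1, "group", "PD_nondep")
    frame.insert(2, "session", "OFF")
    frame["accepted"] = (rng.random(len(frame)) < p).astype(int)
    return frame[model.TRIAL_COLUMNS + ["run"]]
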