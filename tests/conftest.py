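import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from riskychoice import ParameterSet, build_schedule, simulate_choices

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def schedule():
    return build_schedule(seed=0)


@pytest.fixture(scope="session")
def typical_session(schedule):
    """One well-behaved simulated subject-session (169 trials)."""
    return simulate_choices(
        schedule, ParameterSet(lam=1.5, mu=1.0, c=-1.0), seed=11,
        subject_id="S1", group="PD_nondep", session="OFF",
    )


def simulate_pool(n_subjects, lam_mean, mu_mean, c_mean, sds, seed, group="PD_nondep"):
    """Small synthetic pool with per-subject parameters drawn around group means."""
    rng = np.random.default_rng(seed)
    frames, truth = [], []
    for i in range(n_subjects):
        lam = float(np.clip(rng.normal(lam_mean, sds[0]), 0, 10))
        mu = float(np.clip(rng.normal(mu_mean, sds[1]), 0.05, 10))
        c = float(np.clip(rng.normal(c_mean, sds[2]), -10, 10))
        sched = build_schedule(int(rng.integers(2**31)))
        frames.append(
            simulate_choices(
                sched, ParameterSet(lam=lam, mu=mu, c=c), int(rng.integers(2**31)),
                subject_id=f"S{i:03d}", group=group, session="OFF",
            )
        )
        truth.append({"subject_id": f"S{i:03d}", "lam": lam, "mu": mu, "c": c})
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth)
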