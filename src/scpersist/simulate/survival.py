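"""Seeded survival cohorts with covariate-linked quartile hazards.

Each subject draws a continuous covariate (standard normal); the subject's
true quartile of that covariate selects a hazard multiplier, and the event
time is exponential with rate baseline x multiplier. Censoring is
independent exponential, calibrated so the expected censored fraction equals
the configured rate within every quartile (for exponential T with rate l and
exponential C with rate l*c/(1-c), P(C < T) = c).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..survival import quartile_stratify
from .config import SimulationConfig
from .expression import GroundTruth


def simulate_survival(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a survival table (subject_id, time, event, covariate, group)."""
    plan = config.survival_plan
    if plan.censoring_rate >= 1.0:
        raise ValueError("censoring_rate >= 1 leaves no observable events")
    rng = config.rng(2)
    n = plan.n_subjects
    covariate = rng.normal(0.0, 1.0, size=n)
    groups = quartile_stratify(covariate)
    mult = dict(zip(("Q1", "Q2", "Q3", "Q4"), plan.quartile_multipliers))
    rates = np.array([plan.baseline_hazard * mult[g] for g in groups])
    event_times = rng.exponential(1.0 / rates)
    if plan.censoring_rate > 0:
        c = plan.censoring_rate
        cens_times = rng.exponential((1.0 - c) / (rates * c))
        event = (event_times <= cens_times).astype(int)
        time = np.minimum(event_times, cens_times)
    else:
        event = np.ones(n, dtype=int)
        time = event_times
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "covariate": covariate,
            "group": groups,
        }
    )
    truth = GroundTruth(quartile_multipliers=tuple(plan.quartile_multipliers))
    return table, truth
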