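"""Seeded group-structured cell-type composition counts.

One multinomial draw per group (treatment time point) at the configured
total, with the configured category proportions as ground truth.
"""

from __future__ import annotations

import pandas as pd

from .config import SimulationConfig
from .expression import GroundTruth

DEFAULT_GROUP_TOTAL = 300


def simulate_composition(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a groups x categories count table plus the true proportions."""
    plan = config.composition_plan
    if not plan.proportions:
        raise ValueError("composition plan defines no groups")
    rng = config.rng(3)
    categories = sorted({c for props in plan.proportions.values() for c in props})
    rows = {}
    for group, props in plan.proportions.items():
        total = int(plan.group_totals.get(group, DEFAULT_GROUP_TOTAL))
        if total <= 0:
            raise ValueError(f"group {group!r} has non-positive total {total}")
        p = [props.get(c, 0.0) for c in categories]
        rows[group] = rng.multinomial(total, p)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=categories)
    truth = GroundTruth(composition={g: dict(p) for g, p in plan.proportions.items()})
    return table, truth
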