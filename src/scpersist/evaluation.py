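"""End-to-end benchmark computations on synthetic data with known truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage, and returns a summary number: ground-truth recovery rates for the CNV
classifier and the variant filter chain, type-I error rates for the
chi-square and log-rank tests, Wilson-interval coverage, Cox
hazard-ratio CI coverage, and the Kaplan-Meier median error under an
exponential model. Both the test suite and the acceptance script run these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cnv, composition, qc, survival, variants
from .simulate import (
    CompositionPlan,
    SimulationConfig,
    SurvivalPlan,
    cnv_benchmark_config,
    simulate_composition,
    simulate_expression,
    simulate_survival,
    simulate_variants,
)
from .simulate.config import VARIANT_CATEGORIES


def quartile_sizes(n: int = 510, seed: int = 0) -> dict:
    """Quartile group sizes for n subjects with distinct random scores."""
    rng = np.random.default_rng(seed)
    scores = rng.permutation(n).astype(float)  # distinct values
    labels = survival.quartile_stratify(scores)
    sizes = pd.Series(labels).value_counts()
    # Q1 must hold the lowest scores
    q1_max = scores[labels == "Q1"].max()
    rest_min = scores[labels != "Q1"].min()
    return {
        "sizes": tuple(int(sizes[q]) for q in ("Q1", "Q2", "Q3", "Q4")),
        "q1_is_lowest": bool(q1_max < rest_min),
    }


# ---------------------------------------------------------------- variants
def _toy_cells(n_patients: int = 3, cells_per_patient: int = 8) -> pd.DataFrame:
    rows = []
    for p in range(n_patients):
        for c in range(cells_per_patient):
            rows.append(
                {
                    "cell_id": f"P{p}_c{c}",
                    "patient": f"P{p}",
                    "sample": f"P{p}_TN",
                    "time_point": "TN",
                    "cell_type": "epithelial",
                    "cluster": "tumor",
                    "is_reference_control": False,
                }
            )
    return pd.DataFrame(rows)


def variant_chain_recovery(n_plans: int = 100, seed: int = 0) -> float:
    """Fraction of random variant plans for which the filter cascade returns
    exactly the somatic_pathogenic_lung ground-truth key set."""
    rng = np.random.default_rng(seed)
    cells = _toy_cells()
    exact = 0
    for i in range(n_plans):
        plan = {c: int(rng.integers(0, 5)) for c in VARIANT_CATEGORIES}
        config = SimulationConfig(
            seed=int(rng.integers(2**31)), variant_plan=plan, cell_groups=()
        )
        sim = simulate_variants(config, cells)
        kept = variants.run_filter_chain(
            sim.calls, sim.dbsnp, sim.germline, sim.pathogenicity, cells, sim.cosmic
        )
        got = set(variants.calls_to_keys(kept)) if not kept.empty else set()
        if got == sim.truth.keys_of("somatic_pathogenic_lung"):
            exact += 1
    return exact / n_plans


# -------------------------------------------------------------------- CNV
def cnv_classification_accuracy(n_seeds: int = 20, seed: int = 0) -> float:
    """Pooled tumor/non-tumor label accuracy on the CNV benchmark condition
    (100 tumor cells with a +0.5 log2 150-gene gain, 100 normal, 40 controls)."""
    correct = total = 0
    for i in range(n_seeds):
        config = cnv_benchmark_config(seed=seed + i)
        matrix, ann, genes, truth = simulate_expression(config)
        matrix = qc.filter_cells(matrix)
        matrix, ann = qc.filter_samples(matrix, ann)
        norm = qc.log_normalize(matrix)
        norm = norm.loc[~matrix.spikein]  # spike-ins have no chromosomal position
        controls = list(ann.loc[ann["is_reference_control"], "cell_id"])
        centered = cnv.center_relative_expression(norm, genes, controls)
        profile = cnv.smooth_windows(centered, genes)
        calls = cnv.classify_by_dendrogram(profile, controls)
        truth_label = calls["cell_id"].map(
            lambda c: "tumor" if truth.malignant[c] else "nontumor"
        )
        correct += int((calls["label"] == truth_label).sum())
        total += len(calls)
    return correct / total


# -------------------------------------------------------- calibration
def chisq_type1_rate(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the chi-square independence test on null composition
    tables (identical proportions in every group)."""
    props = {"T cell": 0.4, "Macrophage": 0.3, "B cell": 0.2, "NK": 0.1}
    plan = CompositionPlan(
        proportions={tp: dict(props) for tp in ("TN", "RD", "PD")},
        group_totals={tp: 200 for tp in ("TN", "RD", "PD")},
    )
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        config = SimulationConfig(seed=int(rng.integers(2**31)), composition_plan=plan)
        table, _ = simulate_composition(config)
        _, _, p = composition.chisq_independence(table)
        rejections += p < alpha
    return rejections / n_reps


def logrank_type1_rate(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05, n_per_group: int = 100
) -> float:
    """Rejection rate of the 4-group log-rank test under equal hazards."""
    plan = SurvivalPlan(
        n_subjects=4 * n_per_group,
        baseline_hazard=0.02,
        quartile_multipliers=(1.0, 1.0, 1.0, 1.0),
        censoring_rate=0.2,
    )
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        config = SimulationConfig(seed=int(rng.integers(2**31)), survival_plan=plan)
        table, _ = simulate_survival(config)
        _, _, p = survival.logrank_test(table, table["group"])
        rejections += p < alpha
    return rejections / n_reps


def wilson_coverage(
    n_reps: int = 2000, seed: int = 0, n: int = 50, ps=(0.1, 0.5), level: float = 0.95
) -> float:
    """Worst-case empirical coverage of the Wilson interval over the tested
    binomial scenarios, in percent."""
    rng = np.random.default_rng(seed)
    worst = 100.0
    for p in ps:
        ks = rng.binomial(n, p, size=n_reps)
        covered = 0
        for k in ks:
            table = pd.DataFrame({"hit": [int(k)], "miss": [n - int(k)]}, index=["g"])
            ci = composition.fractions_with_ci(table, level=level)
            row = ci[ci["category"] == "hit"].iloc[0]
            covered += row["ci_low"] <= p <= row["ci_high"]
        worst = min(worst, 100.0 * covered / n_reps)
    return worst


# ------------------------------------------------------------- survival
def cox_hr_ci_coverage(
    n_reps: int = 100, seed: int = 0, true_hr: float = 2.0, n_per_group: int = 250
) -> float:
    """Percent of replicates whose Cox Q1-vs-Q4 95% CI covers the true hazard
    ratio (quartile hazards 1, 1, 1, true_hr; no censoring)."""
    plan = SurvivalPlan(
        n_subjects=4 * n_per_group,
        baseline_hazard=0.02,
        quartile_multipliers=(1.0, 1.0, 1.0, true_hr),
        censoring_rate=0.0,
    )
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_reps):
        config = SimulationConfig(seed=int(rng.integers(2**31)), survival_plan=plan)
        table, _ = simulate_survival(config)
        fit = survival.cox_q1_vs_q4(table, table["group"])
        covered += fit["ci_low"] <= true_hr <= fit["ci_high"]
    return 100.0 * covered / n_reps


def km_median_relative_error(
    seed: int = 0, n: int = 500, baseline_hazard: float = 0.02
) -> float:
    """Percent error of the KM median against the exponential closed form
    ln(2)/lambda, with uniform hazards and no censoring."""
    plan = SurvivalPlan(
        n_subjects=n,
        baseline_hazard=baseline_hazard,
        quartile_multipliers=(1.0, 1.0, 1.0, 1.0),
        censoring_rate=0.0,
    )
    config = SimulationConfig(seed=seed, survival_plan=plan)
    table, _ = simulate_survival(config)
    med = survival.km_median(table)
    expected = np.log(2) / baseline_hazard
    return 100.0 * abs(med - expected) / expected
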