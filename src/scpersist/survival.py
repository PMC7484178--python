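"""Survival stratification and testing for signature and burden analyses.

Subjects are stratified into quartiles of a continuous covariate (signature
score, immune-cell fraction) or into mutation-high/low groups, then compared
with Kaplan-Meier curves, the log-rank test, and a Cox proportional-hazards
fit of the lowest versus the highest quartile. Estimation is delegated to
lifelines (Efron handling of tied event times in the Cox fit); the quartile
assignment rule and the fraction-combination column sets are defined here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

#: CIBERSORT LM22 columns combined into the total macrophage fraction
MACROPHAGE_COLUMNS = (
    "Monocytes",
    "Macrophages.M0",
    "Macrophages.M1",
    "Macrophages.M2",
)

#: CIBERSORT LM22 columns combined into the total T/NK fraction
T_NK_COLUMNS = (
    "T.cells.CD8",
    "T.cells.CD4.naive",
    "T.cells.CD4.memory.resting",
    "T.cells.CD4.memory.activated",
    "T.cells.follicular.helper",
    "T.cells.regulatory.Tregs",
    "T.cells.gamma.delta",
    "NK.cells.resting",
    "NK.cells.activated",
)


def quartile_stratify(values) -> np.ndarray:
    """Assign Q1..Q4 labels by ascending value.

    Subjects are sorted ascending (ties broken by stable input order); the
    subject of 0-based rank i goes to quartile floor(4 i / n). Q1 is the
    lowest quartile. For n = 510 this yields group sizes (128, 127, 128, 127).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 subjects for quartiles")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return np.array([QUARTILE_LABELS[(4 * r) // n] for r in ranks], dtype=object)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return records


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table (time, survival, at_risk); censored subjects leave
    the risk set without a step.
    """
    _check_records(records)
    if records.empty:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(), "at_risk": at_risk.to_numpy()}
    )


def km_median(records: pd.DataFrame) -> float:
    """Median survival time (first time S(t) <= 0.5; NaN if never reached)."""
    curve = km_curve(records)
    below = curve[curve["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if not below.empty else float("nan")


def logrank_test(records: pd.DataFrame, groups) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi-square statistic, df, p)."""
    _check_records(records)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if records["event"].sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    res = multivariate_logrank_test(records["time"], g, records["event"])
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def cox_q1_vs_q4(records: pd.DataFrame, groups) -> dict:
    """Cox proportional-hazards fit of Q4 (high) versus Q1 (low).

    The single covariate is an indicator for Q4, so the hazard ratio reads
    "hazard in high expressors relative to low". Returns hazard ratio, Wald
    95% CI and p-value. Both groups must contain at least one event.
    """
    g = pd.Series(np.asarray(groups), index=records.index)
    sub = records[g.isin(["Q1", "Q4"])].copy()
    gsub = g[g.isin(["Q1", "Q4"])]
    if (gsub == "Q1").sum() == 0 or (gsub == "Q4").sum() == 0:
        raise ValueError("both Q1 and Q4 must be non-empty")
    sub["high"] = (gsub == "Q4").astype(int)
    _check_records(sub)
    for label in ("Q1", "Q4"):
        if sub.loc[gsub == label, "event"].sum() == 0:
            raise ValueError(
                f"group {label} has no events; the partial likelihood is monotone"
            )
    cph = CoxPHFitter()
    cph.fit(sub[["time", "event", "high"]], duration_col="time", event_col="event")
    s = cph.summary.loc["high"]
    return {
        "hazard_ratio": float(np.exp(s["coef"])),
        "ci_low": float(np.exp(s["coef lower 95%"])),
        "ci_high": float(np.exp(s["coef upper 95%"])),
        "p": float(s["p"]),
        "log_hr": float(s["coef"]),
    }


def combine_fractions(fractions: pd.DataFrame) -> pd.DataFrame:
    """Subject-level total macrophage and total T/NK fractions.

    Row sums over the fixed deconvolution column sets; columns missing from
    the table are treated as 0 with a warning. Negative fractions are an
    error.
    """
    import warnings

    if (fractions.select_dtypes("number") < 0).any().any():
        raise ValueError("negative fractions")
    out = {}
    for name, cols in (("macrophage", MACROPHAGE_COLUMNS), ("t_nk", T_NK_COLUMNS)):
        present = [c for c in cols if c in fractions.columns]
        absent = set(cols) - set(present)
        if absent:
            warnings.warn(f"missing columns treated as 0: {sorted(absent)}", stacklevel=2)
        out[name] = fractions[present].sum(axis=1) if present else pd.Series(0.0, index=fractions.index)
    res = pd.DataFrame(out)
    if ((res < 0) | (res > 1)).any().any():
        raise ValueError("combined fractions fall outside [0, 1]")
    return res


def median_split(values) -> np.ndarray:
    """High/low labels by the median; ties at the median go low."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 subjects")
    med = np.median(values)
    return np.where(values > med, "high", "low")
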