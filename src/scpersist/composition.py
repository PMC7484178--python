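"""Tumor-microenvironment composition statistics and small validation formulas.

Covers per-cluster patient occupancy, relative cell-type frequencies with
Wilson confidence intervals, chi-square tests of independence across
treatment time points, pairwise composition correlations, the
immunoreactivity score (IRS) used to grade immunohistochemistry, and the
delta-Ct fold change of RT-PCR assays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, pearsonr
from statsmodels.stats.proportion import proportion_confint


def patient_occupancy(cluster_labels, patient_labels) -> pd.Series:
    """Largest single-patient fraction per cluster.

    Occupancy near 1 marks patient-specific clusters (typically malignant);
    shared clusters sit near 1 / n_patients.
    """
    df = pd.DataFrame({"cluster": list(cluster_labels), "patient": list(patient_labels)})
    if df.empty:
        raise ValueError("no cells given")
    counts = df.groupby(["cluster", "patient"]).size()
    totals = df.groupby("cluster").size()
    return (counts.groupby(level="cluster").max() / totals).rename("occupancy")


def fractions_with_ci(
    table: pd.DataFrame,
    level: float = 0.95,
    method: str = "wilson",
    simultaneous: bool = False,
) -> pd.DataFrame:
    """Relative frequency of each category per group with a confidence interval.

    ``table`` holds counts (rows = groups, columns = categories). The interval
    is Wilson by default (``method='wald'`` gives the plain normal interval);
    with ``simultaneous=True`` the per-category level is Bonferroni-adjusted
    across categories so the intervals hold jointly. Bounds are truncated to
    [0, 1].
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    totals = table.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"groups with zero total: {bad}")
    alpha = 1.0 - level
    if simultaneous:
        alpha /= table.shape[1]
    sm_method = {"wilson": "wilson", "wald": "normal"}[method]
    rows = []
    for group, row in table.iterrows():
        n = int(totals[group])
        for cat, k in row.items():
            lo, hi = proportion_confint(int(k), n, alpha=alpha, method=sm_method)
            if k == 0:  # exact boundary; avoids float noise from the solver
                lo = 0.0
            if k == n:
                hi = 1.0
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "count": int(k),
                    "total": n,
                    "fraction": k / n,
                    "ci_low": max(0.0, float(lo)),
                    "ci_high": min(1.0, float(hi)),
                }
            )
    return pd.DataFrame(rows)


def chisq_independence(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns (statistic, degrees of freedom, p-value); no continuity
    correction. Zero expected counts are an error — merge sparse categories
    first.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 categories")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count; merge sparse categories before testing")
    stat, p, dof, _ = chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def composition_correlation(frac_a, frac_b) -> float:
    """Pearson correlation between two composition vectors.

    NaN when either vector is constant (the correlation is undefined).
    """
    a = np.asarray(frac_a, dtype=float)
    b = np.asarray(frac_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(pearsonr(a, b).statistic)


def compute_irs(intensity: int, percent_positive: float) -> int:
    """Immunoreactivity score: staining intensity x percent-positivity coefficient.

    Intensity is graded 0-3; the coefficient is 0 for 0% positive cells,
    1 below 10%, 2 for 10-50%, 3 for 51-80% (values in (50, 51) map up, the
    bins being contiguous), and 4 above 80%. The score ranges 0-12.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer in 0..3")
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError("percent_positive must lie in [0, 100]")
    if percent_positive == 0:
        coeff = 0
    elif percent_positive < 10:
        coeff = 1
    elif percent_positive <= 50:
        coeff = 2
    elif percent_positive <= 80:
        coeff = 3
    else:
        coeff = 4
    return intensity * coeff


def ddct_fold_change(ct_treated: float, ct_control: float) -> float:
    """Delta-Ct fold change: 2^(Ct_control - Ct_treated).

    Each PCR cycle doubles product, so a one-cycle-lower treated Ct means a
    two-fold higher mRNA level. Housekeeping normalization is assumed already
    applied to the inputs.
    """
    if not (np.isfinite(ct_treated) and np.isfinite(ct_control)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_control - ct_treated))
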