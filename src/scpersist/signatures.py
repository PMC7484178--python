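"""Gene-signature scoring and grouped comparisons across treatment time points.

A signature is a named gene list (e.g. alveolar, kynurenine, plasminogen
activation, SERPINE1, gap junction); its score for a cell or sample is the
unweighted mean of log-normalized expression over the signature genes present
in the matrix. Grouped comparisons use two-sided Wilcoxon rank-sum tests
between time points with Holm adjustment across pairs; per-sample mean
matrices, rank-correlation checks against an external reference profile,
dot-plot summaries, and the patient-support post-filter for differential
expression gene lists round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


def read_gmt(path) -> list[GeneSignature]:
    """Load signatures from a GMT file."""
    from gseapy.parser import read_gmt as _read_gmt

    sets = _read_gmt(str(path))
    return [GeneSignature(name, tuple(genes)) for name, genes in sets.items()]


def write_gmt(signatures, path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")


def score_cells(norm: pd.DataFrame, sig: GeneSignature) -> tuple[pd.Series, int]:
    """Mean normalized expression of a signature per cell.

    Returns (scores indexed by cell, number of signature genes missing from
    the matrix). Zero overlap is an error.
    """
    present = [g for g in sig.genes if g in norm.index]
    missing = len(sig.genes) - len(present)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is in the matrix")
    return norm.loc[present].mean(axis=0).rename(sig.name), missing


def pairwise_group_test(scores: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between every pair of groups.

    Holm-adjusted p-values are reported alongside the raw ones. Pairs with a
    group of fewer than 2 observations are skipped with a warning.
    """
    groups = pd.Series(np.asarray(groups), index=scores.index)
    by = {g: scores[groups == g] for g in pd.unique(groups)}
    rows = []
    for a, b in combinations(by, 2):
        if len(by[a]) < 2 or len(by[b]) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: group with < 2 cells", stacklevel=2)
            continue
        xa, xb = by[a].to_numpy(), by[b].to_numpy()
        no_ties = len(np.unique(np.r_[xa, xb])) == len(xa) + len(xb)
        method = "exact" if no_ties and max(len(xa), len(xb)) <= 25 else "asymptotic"
        res = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append({"group_a": a, "group_b": b, "statistic": res.statistic, "p_raw": res.pvalue})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def sample_average_matrix(
    norm: pd.DataFrame, signatures, ann: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample mean expression of signature genes and overall scores.

    Returns (samples x genes, samples x signatures) tables; the gene table is
    restricted to the union of signature genes present in the matrix.
    """
    sample_of = pd.Series(
        ann.set_index("cell_id")["sample"].reindex(norm.columns).to_numpy(),
        index=norm.columns,
    )
    genes = sorted({g for s in signatures for g in s.genes if g in norm.index})
    gene_means = norm.loc[genes].T.groupby(sample_of).mean()
    sig_scores = {}
    for sig in signatures:
        scores, _ = score_cells(norm, sig)
        sig_scores[sig.name] = scores.groupby(sample_of).mean()
    return gene_means, pd.DataFrame(sig_scores)


def spearman_to_reference(
    norm: pd.DataFrame, reference_profile: pd.Series, groups: pd.Series | None = None
) -> tuple[pd.Series, pd.Series | None]:
    """Spearman rank correlation of each cell against a reference mean profile.

    Computed over the genes shared between the matrix and the reference
    (at least 3 required); cells with constant expression over shared genes
    get NaN. Optionally also returns per-group mean correlations.
    """
    shared = [g for g in reference_profile.index if g in norm.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared with the reference profile")
    ref = reference_profile[shared].to_numpy(dtype=float)
    if np.std(ref) == 0:
        raise ValueError("reference profile is constant over shared genes")
    x = norm.loc[shared]
    rhos = {}
    for cell in x.columns:
        v = x[cell].to_numpy(dtype=float)
        rhos[cell] = float("nan") if np.std(v) == 0 else float(spearmanr(v, ref).statistic)
    rho = pd.Series(rhos, name="spearman_rho")
    if groups is None:
        return rho, None
    g = pd.Series(np.asarray(groups), index=rho.index)
    return rho, rho.groupby(g).mean()


def dotplot_stats(norm: pd.DataFrame, genes, groups: pd.Series) -> pd.DataFrame:
    """Per (gene, group) mean scaled expression and fraction of expressing cells.

    Expression is z-scored per gene across all cells before group means
    (zero-variance genes scale to 0); a cell expresses a gene when its
    normalized value is > 0. Genes absent from the matrix are skipped with a
    warning.
    """
    g = pd.Series(np.asarray(groups), index=norm.columns)
    rows = []
    for gene in genes:
        if gene not in norm.index:
            warnings.warn(f"gene {gene!r} absent from matrix; skipped", stacklevel=2)
            continue
        v = norm.loc[gene]
        sd = v.std(ddof=0)
        z = (v - v.mean()) / sd if sd > 0 else pd.Series(0.0, index=v.index)
        for group in pd.unique(g):
            in_g = g == group
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "mean_scaled": float(z[in_g].mean()),
                    "frac_expressing": float((v[in_g] > 0).mean()),
                }
            )
    return pd.DataFrame(rows)


def patient_support_filter(
    de_genes: pd.DataFrame,
    norm: pd.DataFrame,
    ann: pd.DataFrame,
    min_patients: dict,
) -> pd.DataFrame:
    """Drop differentially expressed genes explained by too few patients.

    For each gene (table columns gene/group), count the distinct patients —
    among cells of the gene's group — with at least one cell expressing it
    (normalized value > 0); keep the gene iff that count meets the group's
    threshold. Guards against patient-specific effects masquerading as
    treatment-time-point signal.
    """
    cells = ann.set_index("cell_id")
    keep = []
    for _, row in de_genes.iterrows():
        group = row["group"]
        if group not in min_patients:
            raise ValueError(f"no patient-support threshold for group {group!r}")
        gene = row["gene"]
        if gene not in norm.index:
            keep.append(False)
            continue
        in_group = cells.index[cells["time_point"] == group]
        in_group = [c for c in in_group if c in norm.columns]
        expr = norm.loc[gene, in_group]
        patients = cells.loc[expr.index[expr > 0], "patient"].nunique()
        keep.append(patients >= min_patients[group])
    return de_genes.loc[keep].reset_index(drop=True)
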