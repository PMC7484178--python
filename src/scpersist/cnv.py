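"""Expression-inferred CNV profiling and tumor/non-tumor classification.

Large-scale copy-number changes leave a footprint in expression: genes inside
an amplified (deleted) region are, on average, up (down) relative to diploid
cells. Ordering expressed genes along each chromosome, centering each gene on
a reference population of presumed-diploid stromal cells, and smoothing with a
100-gene moving average turns that footprint into a per-cell chromosomal
profile. Cells are then Ward-clustered on their profiles and the dendrogram is
cut at the smallest number of clusters at which (all but a tolerated few of)
the spiked-in stromal controls co-occur in one cluster; cells sharing the
control cluster are called non-tumor, the rest tumor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


def order_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Sort a gene annotation (gene_id, chromosome, start) by genomic position.

    Chromosomes keep their order of first appearance in the table; genes are
    sorted by start within each chromosome.
    """
    for col in ("gene_id", "chromosome", "start"):
        if col not in genes.columns:
            raise ValueError(f"gene annotation missing column {col!r}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    chrom_order = {c: i for i, c in enumerate(pd.unique(genes["chromosome"]))}
    key = genes["chromosome"].map(chrom_order)
    return (
        genes.assign(_ck=key)
        .sort_values(["_ck", "start"], kind="stable")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )


@dataclass
class CnvProfile:
    """Cells x ordered-gene-windows smoothed relative expression."""

    matrix: pd.DataFrame  # cells x windows (one window anchored per gene)
    windows: pd.DataFrame  # per window: gene_id, chromosome
    reference_cells: list[str]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.matrix.index)


def center_relative_expression(
    norm: pd.DataFrame,
    genes: pd.DataFrame,
    reference_cells,
    cap: float = 3.0,
) -> pd.DataFrame:
    """Center log-normalized expression on a reference population.

    Each gene's values are shifted by minus its mean over ``reference_cells``
    (the presumed-diploid anchor), then symmetrically capped to ``[-cap, cap]``
    so single outlier genes cannot dominate a window. Genes absent from the
    annotation are dropped with a warning. Returns a genes x cells frame in
    genomic order.
    """
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference cell set is empty")
    missing_ref = set(reference_cells) - set(norm.columns)
    if missing_ref:
        raise ValueError(f"reference cells absent from matrix: {sorted(missing_ref)[:5]}")
    ordered = order_genes(genes)
    known = ordered["gene_id"].isin(norm.index)
    if not known.all():
        n_lost = int((~known).sum())
        warnings.warn(f"{n_lost} annotated genes absent from the matrix; dropped", stacklevel=2)
    unannotated = set(norm.index) - set(ordered["gene_id"])
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} matrix genes missing from annotation; dropped",
            stacklevel=2,
        )
    order = [g for g in ordered["gene_id"] if g in norm.index]
    x = norm.loc[order]
    centered = x.sub(x[reference_cells].mean(axis=1), axis=0)
    return centered.clip(lower=-cap, upper=cap)


def smooth_windows(
    centered: pd.DataFrame, genes: pd.DataFrame, window: int = 100
) -> CnvProfile:
    """Moving average of centered expression along each chromosome.

    One window is anchored at every gene position i, covering genes
    ``[i - w//2, i + w//2]`` truncated at chromosome boundaries (chromosomes
    shorter than the window simply average all their genes). Returns a
    cells x windows profile.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ordered = order_genes(genes)
    ordered = ordered[ordered["gene_id"].isin(centered.index)]
    half = window // 2
    blocks = []
    meta = []
    for chrom, sub in ordered.groupby("chromosome", sort=False):
        ids = list(sub["gene_id"])
        n = len(ids)
        if n == 0:
            warnings.warn(f"chromosome {chrom} has no annotated genes; skipped", stacklevel=2)
            continue
        vals = centered.loc[ids].to_numpy(dtype=float)  # genes x cells
        csum = np.vstack([np.zeros((1, vals.shape[1])), np.cumsum(vals, axis=0)])
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half, n - 1) + 1
        smoothed = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
        blocks.append(smoothed)
        meta.append(pd.DataFrame({"gene_id": ids, "chromosome": chrom}))
    if not blocks:
        raise ValueError("no chromosome yielded any window")
    mat = np.vstack(blocks).T  # cells x windows
    windows = pd.concat(meta, ignore_index=True)
    return CnvProfile(
        matrix=pd.DataFrame(mat, index=list(centered.columns), columns=list(windows["gene_id"])),
        windows=windows,
        reference_cells=[],
    )


def cnv_score(profile: CnvProfile) -> pd.Series:
    """Extent of CNV signal per cell: mean of squared window values.

    Zero iff every window is zero; grows with both the breadth and the
    amplitude of chromosomal deviation.
    """
    if profile.matrix.shape[1] == 0:
        raise ValueError("empty CNV profile")
    return (profile.matrix**2).mean(axis=1).rename("cnv_score")


def classify_by_dendrogram(
    profile: CnvProfile, controls, tolerance: int = 1
) -> pd.DataFrame:
    """Tumor/non-tumor calls from a dendrogram cut anchored on spiked controls.

    Ward linkage on Euclidean distance between window profiles; k = 2, 3, ...
    is scanned and the smallest k (highest cut) is selected at which all but at
    most ``tolerance`` controls fall in a single cluster. Cells sharing that
    control cluster are labeled ``nontumor``; everything else ``tumor``.

    Returns a table (cell_id, label, cnv_score, chosen_k).
    """
    controls = set(controls)
    cells = profile.cell_ids
    is_control = np.array([c in controls for c in cells])
    n_controls = int(is_control.sum())
    if n_controls < 2:
        raise ValueError("need at least 2 control cells")
    if n_controls == len(cells):
        raise ValueError("need at least 1 non-control cell")
    Z = linkage(profile.matrix.to_numpy(), method="ward")
    scores = cnv_score(profile)
    n = len(cells)
    for k in range(2, n + 1):
        assign = fcluster(Z, t=k, criterion="maxclust")
        counts = pd.Series(assign[is_control]).value_counts()
        top_cluster = counts.index[0]
        if n_controls - int(counts.iloc[0]) <= tolerance:
            labels = np.where(assign == top_cluster, "nontumor", "tumor")
            return pd.DataFrame(
                {
                    "cell_id": cells,
                    "label": labels,
                    "cnv_score": scores.to_numpy(),
                    "chosen_k": k,
                }
            )
    raise ValueError(
        "no dendrogram cut keeps the controls together; consider raising tolerance"
    )


def group_mean_cnv(calls: pd.DataFrame, ann: pd.DataFrame, by: str = "time_point") -> pd.DataFrame:
    """Mean CNV score per sample or per treatment time point."""
    merged = calls.merge(ann[["cell_id", by]], on="cell_id", how="inner")
    out = merged.groupby(by)["cnv_score"].agg(["mean", "size"])
    return out.rename(columns={"mean": "mean_cnv_score", "size": "n_cells"})
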