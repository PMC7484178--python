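"""Count-matrix container and cell/sample quality control.

Implements the cohort's QC rules: cells with fewer than 500 detected genes
or fewer than 50,000 reads are excluded, and samples left with fewer than
10 cells after cell-level QC are dropped entirely. ERCC spike-in rows are
technical controls and are excluded from detected-gene and read tallies and
from normalization totals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIME_POINTS = ("TN", "RD", "PD")

#: columns every cell annotation table must carry
ANNOTATION_COLUMNS = (
    "cell_id",
    "patient",
    "sample",
    "time_point",
    "cell_type",
    "cluster",
    "is_reference_control",
)


@dataclass
class CountMatrix:
    """genes x cells integer count matrix with ERCC spike-in flags.

    Parameters
    ----------
    values
        Non-negative integer counts, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique identifiers matching the matrix dimensions.
    spikein
        Boolean per-gene flag marking ERCC spike-in rows.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    spikein: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.spikein is None:
            self.spikein = np.zeros(self.values.shape[0], dtype=bool)
        self.spikein = np.asarray(self.spikein, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("id lists inconsistent with matrix dimensions")
        if len(self.spikein) != n_genes:
            raise ValueError("spikein flags inconsistent with gene count")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.values[:, mask], self.gene_ids, self.cell_ids[mask], self.spikein
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.values[mask], self.gene_ids[mask], self.cell_ids, self.spikein[mask]
        )

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of endogenous (non-spike-in) genes with count > 0 per cell."""
        return (self.values[~self.spikein] > 0).sum(axis=0)

    def reads_per_cell(self) -> np.ndarray:
        """Total endogenous reads per cell (spike-ins excluded)."""
        return self.values[~self.spikein].sum(axis=0)


def validate_annotation(ann: pd.DataFrame, matrix: CountMatrix | None = None) -> pd.DataFrame:
    """Check a cell annotation table and (optionally) its companion matrix."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    bad_tp = set(ann["time_point"]) - set(TIME_POINTS)
    if bad_tp:
        raise ValueError(f"time_point must be one of {TIME_POINTS}; got {sorted(bad_tp)}")
    if ann["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in annotation")
    if matrix is not None:
        unknown = set(matrix.cell_ids) - set(ann["cell_id"])
        if unknown:
            raise ValueError(f"{len(unknown)} matrix cells absent from annotation")
    return ann


def filter_cells(
    m: CountMatrix, min_genes: int = 500, min_reads: int = 50_000
) -> CountMatrix:
    """Drop low-quality cells.

    A cell is kept iff it has at least ``min_genes`` detected endogenous genes
    AND at least ``min_reads`` endogenous reads. Spike-in rows count toward
    neither tally. Cell order is preserved.
    """
    if min_genes < 0 or min_reads < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (m.detected_genes_per_cell() >= min_genes) & (m.reads_per_cell() >= min_reads)
    if not keep.any():
        warnings.warn("all cells removed by QC filter", stacklevel=2)
    return m.subset_cells(keep)


def filter_samples(
    m: CountMatrix, ann: pd.DataFrame, min_cells: int = 10
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop whole samples with fewer than ``min_cells`` cells after QC.

    Strictly-less-than semantics: a sample with exactly ``min_cells`` cells
    survives.
    """
    ann = ann.set_index("cell_id").loc[list(m.cell_ids)].reset_index()
    sizes = ann.groupby("sample")["cell_id"].size()
    small = set(sizes.index[sizes < min_cells])
    keep = ~ann["sample"].isin(small).to_numpy()
    if small:
        logger.info("removing %d samples with < %d cells: %s", len(small), min_cells, sorted(small))
    return m.subset_cells(keep), ann.loc[keep].reset_index(drop=True)


def log_normalize(m: CountMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Per-cell log normalization: ln(1 + scale * count / cell_total).

    ``cell_total`` is the cell's endogenous read count; spike-in rows are
    normalized by the same endogenous total so per-cell values stay comparable.
    Returns a genes x cells DataFrame of floats.
    """
    totals = m.reads_per_cell().astype(float)
    zero = totals == 0
    if zero.any():
        bad = list(m.cell_ids[zero])
        raise ValueError(f"cells with zero endogenous counts cannot be normalized: {bad}")
    norm = np.log1p(scale * m.values / totals[np.newaxis, :])
    return pd.DataFrame(norm, index=list(m.gene_ids), columns=list(m.cell_ids))


def unique_gene_stats(m: CountMatrix, groups: pd.Series | None = None) -> dict:
    """Per-cell detected-gene and read statistics.

    Returns a dict with a per-cell table, optional per-group means, and the
    Pearson correlation between detected genes and reads (NaN when either
    vector is constant).
    """
    genes = m.detected_genes_per_cell()
    reads = m.reads_per_cell()
    per_cell = pd.DataFrame(
        {"cell_id": list(m.cell_ids), "n_genes": genes, "n_reads": reads}
    )
    out: dict = {"per_cell": per_cell}
    if groups is not None:
        g = np.asarray(groups)
        out["group_means"] = (
            per_cell.assign(group=g).groupby("group")[["n_genes", "n_reads"]].mean()
        )
    if m.n_cells < 3:
        raise ValueError("need at least 3 cells for the depth correlation")
    if np.std(genes) == 0 or np.std(reads) == 0:
        out["pearson_r"] = float("nan")
    else:
        from scipy.stats import pearsonr

        out["pearson_r"] = float(pearsonr(genes, reads).statistic)
    return out
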