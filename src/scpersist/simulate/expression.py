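"""Seeded generation of cell-type-structured count matrices with implanted CNVs.

Counts are drawn per gene and cell from a negative binomial (default
dispersion 0.3, Poisson optional) around a per-cell expected profile built
from: a per-gene baseline weight, a per-cell-type log-normal expression
offset, a uniform per-cell library size, and — in tumor cells — a 2^effect
multiplier over every gene inside an implanted CNV segment. Independent
dropout zeroes endogenous entries; ERCC spike-in rows are appended,
Poisson-distributed and exempt from dropout (they enter the lysate before
reverse transcription, so their detection is modeled as depth-limited only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..qc import CountMatrix
from .config import SimulationConfig

#: nominal gene span in bases; genes are laid out on a regular grid
GENE_SPAN = 1_000
GENE_STRIDE = 1_500
ERCC_LENGTH = 800


@dataclass
class GroundTruth:
    """What the generator implanted, for downstream recovery checks."""

    malignant: dict = field(default_factory=dict)  # cell_id -> bool
    segments: tuple = ()
    variant_category: dict = field(default_factory=dict)  # key -> category
    variant_cells: dict = field(default_factory=dict)  # key -> tuple of cell ids
    quartile_multipliers: tuple = ()
    composition: dict = field(default_factory=dict)

    def keys_of(self, category: str) -> set:
        return {k for k, c in self.variant_category.items() if c == category}


def build_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene layout: regular grid along each chromosome (BED-style
    0-based starts)."""
    rows = []
    i = 0
    for chrom, n in config.chromosomes:
        for j in range(n):
            rows.append((f"g{i:05d}", chrom, j * GENE_STRIDE, j * GENE_STRIDE + GENE_SPAN))
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def ercc_ids(config: SimulationConfig) -> list[str]:
    return [f"ERCC-{i + 1:05d}" for i in range(config.n_ercc)]


def simulate_expression(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (CountMatrix, CellAnnotation, GeneAnnotation, GroundTruth).

    Identical config and seed yield byte-identical output.
    """
    if not config.cell_groups:
        raise ValueError("config defines no cell groups")
    for g in config.cell_groups:
        if g.n_cells <= 0:
            raise ValueError(f"cell group {g.label!r} has zero cells")
    rng = config.rng(0)
    genes = build_gene_annotation(config)
    n_genes = config.n_genes

    # per-gene baseline weights: gamma-distributed relative expression levels
    base = rng.gamma(shape=1.0, scale=config.baseline_mean, size=n_genes)
    base = np.maximum(base, 1e-4 * config.baseline_mean)

    # per-cell-type log-normal offsets, drawn once per type (order of first
    # appearance), shared by all cells of that type
    type_effect: dict[str, np.ndarray] = {}
    for g in config.cell_groups:
        if g.cell_type not in type_effect:
            type_effect[g.cell_type] = np.exp(
                rng.normal(0.0, config.cell_type_sigma, size=n_genes)
            )

    # CNV multiplier over segment genes, applied to tumor cells only
    chrom_offset = {}
    off = 0
    for chrom, n in config.chromosomes:
        chrom_offset[chrom] = off
        off += n
    cnv_mult = np.ones(n_genes)
    for seg in config.cnv_segments:
        lo = chrom_offset[seg.chromosome] + seg.start_gene
        cnv_mult[lo : lo + seg.length] *= 2.0**seg.log2_effect

    # spike-in weights: log-uniform across a 100x abundance range, scaled to
    # a fixed 3% of each cell's library
    if config.n_ercc > 0:
        ercc_w = np.exp(rng.uniform(np.log(1.0), np.log(100.0), size=config.n_ercc))
        ercc_w = 0.03 * ercc_w / ercc_w.sum()

    blocks = []
    cells = []
    truth = GroundTruth(segments=config.cnv_segments)
    for group in config.cell_groups:
        weights = base * type_effect[group.cell_type]
        if group.is_tumor:
            weights = weights * cnv_mult
        for sh in config.expression_shifts:
            if sh.time_point == group.time_point and (group.is_tumor or not sh.tumor_only):
                weights = weights.copy()
                weights[sh.start_gene : sh.start_gene + sh.length] *= 2.0**sh.log2_effect
        if config.library_size_range is not None:
            lo, hi = config.library_size_range
            libs = rng.integers(int(lo), int(hi) + 1, size=group.n_cells).astype(float)
            mu = np.outer(weights / weights.sum(), libs)
        else:
            mu = np.tile(weights[:, None], (1, group.n_cells))
            libs = mu.sum(axis=0)
        counts = _draw_counts(rng, mu, config)
        if config.dropout_rate > 0:
            # expression-dependent dropout: the zero-inflation probability is
            # dropout_rate for a barely-expressed gene and decays geometrically
            # with expected counts (Smart-seq2 dropout is depth-limited, so
            # well-expressed genes are essentially never lost); dropout_rate = 1
            # degenerates to zeroing everything
            p_drop = config.dropout_rate ** (1.0 + mu / config.dropout_scale)
            keep = rng.random(counts.shape) >= p_drop
            counts = counts * keep
        if config.n_ercc > 0:
            ercc_mu = np.outer(ercc_w, libs)
            ercc_counts = rng.poisson(ercc_mu)
            counts = np.vstack([counts, ercc_counts])
        blocks.append(counts)
        for i in range(group.n_cells):
            cid = f"{group.label}_c{i:03d}"
            cells.append(
                {
                    "cell_id": cid,
                    "patient": group.patient,
                    "sample": group.sample,
                    "time_point": group.time_point,
                    "cell_type": group.cell_type,
                    "cluster": group.label,
                    "is_reference_control": group.is_control,
                }
            )
            truth.malignant[cid] = bool(group.is_tumor)
    ann = pd.DataFrame(cells)
    gene_ids = list(genes["gene_id"]) + ercc_ids(config)
    spikein = np.array([False] * n_genes + [True] * config.n_ercc)
    matrix = CountMatrix(
        np.hstack(blocks).astype(np.int64),
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array([c["cell_id"] for c in cells], dtype=object),
        spikein=spikein,
    )
    return matrix, ann, genes, truth


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.count_law == "poisson" or config.nb_dispersion == 0:
        return rng.poisson(mu)
    # NB with variance mu + dispersion * mu^2
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)
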