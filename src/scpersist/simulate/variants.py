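"""Seeded generation of per-cell variant calls and the reference catalogs.

Every generated variant carries a ground-truth category that determines
where it surfaces:

- ``dbsnp``: present in the dbSNP-like population catalog;
- ``germline``: present in its patient's germline profile;
- ``somatic_pathogenic_lung``: COSMIC-annotated to "Lung" with pathogenicity
  score > 0.7 — the only category the downstream filter cascade retains;
- ``somatic_benign``: COSMIC "Lung" but score <= 0.7;
- ``somatic_nonlung``: score > 0.7 but COSMIC-annotated to another tissue;
- ``ercc_artifact``: a call landing on a spike-in contig (false positive by
  construction).

Positions are drawn uniformly within genes without replacement (keys are
globally unique; collisions are re-drawn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..variants import VariantCatalog, empty_calls
from .config import SimulationConfig, VARIANT_CATEGORIES
from .expression import (
    ERCC_LENGTH,
    GENE_SPAN,
    GroundTruth,
    build_gene_annotation,
    ercc_ids,
)

BASES = ("A", "C", "G", "T")

NONLUNG_TISSUES = ("Breast", "Skin", "Colon")


@dataclass
class VariantSimulation:
    """All in-memory outputs of the variant generator."""

    calls: pd.DataFrame  # long table over all cells
    germline: dict  # patient -> VariantCatalog
    dbsnp: VariantCatalog
    cosmic: VariantCatalog
    pathogenicity: VariantCatalog
    coverage: pd.DataFrame  # sample, gene, reads
    ercc_coverage: pd.DataFrame  # cell_id, covered_bases
    gene_map: dict  # key -> gene symbol
    truth: GroundTruth = field(default_factory=GroundTruth)


def simulate_variants(config: SimulationConfig, cells: pd.DataFrame) -> VariantSimulation:
    """Generate per-cell calls, catalogs, coverage tables and ground truth."""
    if cells.empty:
        raise ValueError("need at least one cell")
    if cells["patient"].isna().any():
        raise ValueError("cells without patient labels")
    rng = config.rng(1)
    genes = build_gene_annotation(config)
    patients = list(pd.unique(cells["patient"]))
    plan = {c: int(config.variant_plan.get(c, 0)) for c in VARIANT_CATEGORIES}

    used_keys: set = set()
    records = []  # (key, category, patient, gene_symbol)
    for category in VARIANT_CATEGORIES:
        for _ in range(plan[category]):
            key, gene_symbol = _draw_key(rng, config, genes, category, used_keys)
            used_keys.add(key)
            patient = patients[int(rng.integers(len(patients)))]
            records.append((key, category, patient, gene_symbol))

    dbsnp_keys, cosmic_tissues, scores, gene_map = set(), {}, {}, {}
    germline: dict[str, set] = {p: set() for p in patients}
    truth = GroundTruth()
    for key, category, patient, gene_symbol in records:
        truth.variant_category[key] = category
        if gene_symbol is not None:
            gene_map[key] = gene_symbol
        if category == "dbsnp":
            dbsnp_keys.add(key)
        elif category == "germline":
            germline[patient].add(key)
        elif category in ("somatic_pathogenic_lung", "somatic_benign", "somatic_nonlung"):
            lo, hi = config.pathogenicity_ranges[category]
            scores[key] = float(rng.uniform(lo, hi))
            if category == "somatic_nonlung":
                cosmic_tissues[key] = {NONLUNG_TISSUES[int(rng.integers(len(NONLUNG_TISSUES)))]}
            else:
                tissues = {"Lung"}
                if rng.random() < 0.3:  # shared-tissue annotations occur in COSMIC
                    tissues.add(NONLUNG_TISSUES[int(rng.integers(len(NONLUNG_TISSUES)))])
                cosmic_tissues[key] = tissues

    # assign variants to cells of their patient (artifacts to any cell)
    call_rows = []
    by_patient = {p: list(cells.loc[cells["patient"] == p, "cell_id"]) for p in patients}
    all_cells = list(cells["cell_id"])
    for key, category, patient, _ in records:
        pool = all_cells if category == "ercc_artifact" else by_patient[patient]
        carriers = [c for c in pool if rng.random() < config.variant_carrier_rate]
        if not carriers:
            carriers = [pool[int(rng.integers(len(pool)))]]
        truth.variant_cells[key] = tuple(carriers)
        chrom, pos, ref, alt = key
        for cid in carriers:
            total = int(1 + rng.poisson(config.coverage_depth))
            alt_depth = int(max(1, rng.binomial(total, 0.5)))
            call_rows.append((cid, chrom, pos, ref, alt, alt_depth, total))
    calls = (
        pd.DataFrame(
            call_rows,
            columns=["cell_id", "chrom", "pos", "ref", "alt", "alt_depth", "total_depth"],
        )
        if call_rows
        else empty_calls()
    )

    coverage = _coverage_table(rng, config, cells, calls, gene_map)
    ercc_cov = pd.DataFrame(
        {
            "cell_id": all_cells,
            "covered_bases": rng.integers(5_000, 20_001, size=len(all_cells)),
        }
    )
    return VariantSimulation(
        calls=calls,
        germline={p: VariantCatalog(keys=k) for p, k in germline.items() if k},
        dbsnp=VariantCatalog(keys=dbsnp_keys),
        cosmic=VariantCatalog(tissues=cosmic_tissues, genes=dict(gene_map)),
        pathogenicity=VariantCatalog(scores=scores),
        coverage=coverage,
        ercc_coverage=ercc_cov,
        gene_map=gene_map,
        truth=truth,
    )


def _draw_key(rng, config, genes, category, used):
    """Uniform position within a random gene (or spike-in contig); re-drawn on
    key collision so (chrom, pos, ref, alt) is globally unique."""
    for _ in range(10_000):
        if category == "ercc_artifact":
            contig = ercc_ids(config)[int(rng.integers(config.n_ercc))]
            pos = int(rng.integers(1, ERCC_LENGTH + 1))
            gene_symbol = None
        else:
            row = genes.iloc[int(rng.integers(len(genes)))]
            contig = row["chromosome"]
            pos = int(row["start"]) + 1 + int(rng.integers(GENE_SPAN))
            gene_symbol = row["gene_id"]
        ref, alt = rng.choice(len(BASES), size=2, replace=False)
        key = (contig, pos, BASES[ref], BASES[alt])
        if key not in used:
            return key, gene_symbol
    raise RuntimeError("could not draw a unique variant key")


def _coverage_table(rng, config, cells, calls, gene_map):
    """Per (sample, gene) region read totals consistent with the drawn calls.

    Coverage at variant-bearing genes always exceeds the summed alt depths;
    a random tenth of the remaining (sample, gene) pairs get zero coverage so
    the NC state is exercised.
    """
    samples = list(pd.unique(cells["sample"]))
    genes_of_interest = sorted(set(gene_map.values()))
    if not genes_of_interest:
        return pd.DataFrame(columns=["sample", "gene", "reads"])
    sample_of = dict(zip(cells["cell_id"], cells["sample"]))
    alt_sum: dict[tuple, float] = {}
    if not calls.empty:
        from ..variants import calls_to_keys

        keys = calls_to_keys(calls)
        for (cid, depth), key in zip(calls[["cell_id", "alt_depth"]].itertuples(index=False), keys):
            gene = gene_map.get(key)
            if gene is None:
                continue
            sk = (sample_of[cid], gene)
            alt_sum[sk] = alt_sum.get(sk, 0.0) + float(depth)
    rows = []
    n_cells_of = cells.groupby("sample")["cell_id"].size().to_dict()
    for s in samples:
        for g in genes_of_interest:
            floor = alt_sum.get((s, g), 0.0)
            if floor > 0:
                reads = floor + rng.poisson(config.coverage_depth * n_cells_of[s] * 0.5)
            elif rng.random() < 0.1:
                reads = 0.0
            else:
                reads = float(rng.poisson(config.coverage_depth * n_cells_of[s] * 0.5))
            rows.append((s, g, reads))
    return pd.DataFrame(rows, columns=["sample", "gene", "reads"])
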