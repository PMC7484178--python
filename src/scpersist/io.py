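"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as MatrixMarket (.mtx) plus gene/cell TSVs or as a
single dense TSV; gene annotation as BED (0-based half-open); variant calls
and catalogs as VCF 4.2 (read through cyvcf2); COSMIC-like and
pathogenicity catalogs as TSV; everything tabular as CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .qc import CountMatrix
from .variants import VariantCatalog


# ---------------------------------------------------------------- counts
def write_counts_mtx(m: CountMatrix, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), scipy.sparse.csr_matrix(m.values))
    pd.DataFrame({"gene_id": list(m.gene_ids), "is_spikein": m.spikein.astype(int)}).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"cell_id": list(m.cell_ids)}).to_csv(
        os.path.join(outdir, "cells.tsv"), sep="\t", index=False
    )


def read_counts_mtx(outdir) -> CountMatrix:
    values = scipy.io.mmread(os.path.join(outdir, "matrix.mtx")).toarray().astype(np.int64)
    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    cells = pd.read_csv(os.path.join(outdir, "cells.tsv"), sep="\t")
    return CountMatrix(
        values,
        gene_ids=genes["gene_id"].to_numpy(dtype=object),
        cell_ids=cells["cell_id"].to_numpy(dtype=object),
        spikein=genes["is_spikein"].to_numpy(dtype=bool),
    )


def write_counts_tsv(m: CountMatrix, path) -> None:
    df = pd.DataFrame(m.values, index=list(m.gene_ids), columns=list(m.cell_ids))
    df.insert(0, "is_spikein", m.spikein.astype(int))
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    spikein = df.pop("is_spikein").to_numpy(dtype=bool)
    return CountMatrix(
        df.to_numpy(dtype=np.int64),
        gene_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
        spikein=spikein,
    )


# ------------------------------------------------------------------ BED
def write_bed(genes: pd.DataFrame, path) -> None:
    """Gene annotation as BED: chrom, start, end (0-based half-open), gene_id."""
    genes[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "start", "end", "gene_id"])
    return df[["gene_id", "chromosome", "start", "end"]]


# ------------------------------------------------------------------ VCF
_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
"""


def _contig_lines(contigs: dict) -> str:
    return "".join(f"##contig=<ID={c},length={int(n)}>\n" for c, n in contigs.items())


def write_vcf(records: pd.DataFrame, path, contigs: dict, sample: str | None = None) -> None:
    """Write calls as VCF 4.2; sites-only when ``sample`` is None.

    ``records`` needs columns chrom/pos/ref/alt and, with a sample,
    alt_depth/total_depth (emitted as AD/DP).
    """
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample is not None:
        cols += f"\tFORMAT\t{sample}"
    order = {c: i for i, c in enumerate(contigs)}
    records = records.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(contigs))
        fh.write(cols + "\n")
        for _, r in records.iterrows():
            line = f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t."
            if sample is not None:
                ad_ref = int(r["total_depth"] - r["alt_depth"])
                line += f"\tGT:AD:DP\t0/1:{ad_ref},{int(r['alt_depth'])}:{int(r['total_depth'])}"
            fh.write(line + "\n")


def write_cell_vcfs(calls: pd.DataFrame, outdir, contigs: dict) -> dict:
    """One VCF per cell; returns cell_id -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for cell_id, sub in calls.groupby("cell_id"):
        path = os.path.join(outdir, f"{cell_id}.vcf")
        write_vcf(sub, path, contigs, sample=str(cell_id))
        paths[str(cell_id)] = path
    return paths


def write_catalog_vcf(catalog: VariantCatalog, path, contigs: dict) -> None:
    records = pd.DataFrame(sorted(catalog.keys), columns=["chrom", "pos", "ref", "alt"])
    write_vcf(records, path, contigs)


def read_catalog_vcf(path) -> VariantCatalog:
    from cyvcf2 import VCF

    keys = set()
    vcf = VCF(str(path))
    for rec in vcf:
        for alt in rec.ALT:
            keys.add((rec.CHROM, rec.POS, rec.REF, alt))
    vcf.close()
    return VariantCatalog(keys=keys)


# ----------------------------------------------------------- catalogs TSV
def write_cosmic_tsv(catalog: VariantCatalog, path) -> None:
    rows = [
        {
            "chrom": k[0],
            "pos": k[1],
            "ref": k[2],
            "alt": k[3],
            "tissues": ";".join(sorted(catalog.tissues.get(k, set()))),
            "gene": catalog.genes.get(k, ""),
        }
        for k in sorted(catalog.keys)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cosmic_tsv(path) -> VariantCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    tissues, genes = {}, {}
    for _, r in df.iterrows():
        key = (r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        tissues[key] = set(str(r["tissues"]).split(";")) if pd.notna(r["tissues"]) else set()
        if pd.notna(r.get("gene")) and r.get("gene"):
            genes[key] = r["gene"]
    return VariantCatalog(tissues=tissues, genes=genes)


def write_scores_tsv(catalog: VariantCatalog, path) -> None:
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "score": s}
        for k, s in sorted(catalog.scores.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> VariantCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    scores = {
        (r["chrom"], int(r["pos"]), r["ref"], r["alt"]): float(r["score"])
        for _, r in df.iterrows()
    }
    return VariantCatalog(scores=scores)


def contigs_for(config) -> dict:
    """Contig header lengths for a simulation config (genes grid + ERCCs)."""
    from .simulate.expression import ERCC_LENGTH, GENE_STRIDE, ercc_ids

    out = {c: n * GENE_STRIDE + GENE_STRIDE for c, n in config.chromosomes}
    out.update({e: ERCC_LENGTH for e in ercc_ids(config)})
    return out
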