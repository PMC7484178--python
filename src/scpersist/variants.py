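"""Per-cell somatic variant filtering and mutation-matrix construction.

Variant calls made on single-cell transcriptomes are dominated by germline
polymorphism and technical artifact. The cascade implemented here reduces
them to reportable somatic events:

1. remove calls present in a dbSNP-like population catalog;
2. subtract each patient's germline calls from that patient's cells
   (patients without a germline profile pass through, with a logged notice);
3. keep only calls with a pathogenicity score strictly above 0.7
   (unscored calls are removed);
4. keep only calls annotated to the tumor tissue ("Lung") in a COSMIC-like
   catalog.

Surviving calls are aggregated into a samples x genes mutant-read-ratio
matrix whose entries are NC ("no coverage") wherever a sample has zero reads
over the region — NC is a third state, never conflated with ratio 0.
ERCC spike-in contigs carry no real variation, so any call landing on them
estimates the per-cell false-positive rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of a variant call table
CALL_COLUMNS = ("cell_id", "chrom", "pos", "ref", "alt", "alt_depth", "total_depth")

#: sentinel for the no-coverage state in mutation matrices
NC = "NC"


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Left-aligned minimal representation of a variant key.

    Trims shared trailing then leading bases (keeping at least one of each
    allele), adjusting the position for trimmed leading bases. Catalog
    membership is always tested on normalized keys, so representation drift
    between callers and catalogs cannot produce false mismatches.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), int(pos), ref, alt)


def calls_to_keys(calls: pd.DataFrame) -> pd.Series:
    """Normalized key per call row."""
    return pd.Series(
        [
            normalize_key(c, p, r, a)
            for c, p, r, a in zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"])
        ],
        index=calls.index,
        dtype=object,
    )


@dataclass
class VariantCatalog:
    """A keyed set of variants with optional annotations.

    ``keys`` hold normalized (chrom, pos, ref, alt) tuples. ``tissues`` maps a
    key to its set of tissue labels, ``scores`` to a pathogenicity score in
    [0, 1], ``genes`` to a gene symbol.
    """

    keys: set = field(default_factory=set)
    tissues: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keys = {normalize_key(*k) for k in self.keys}
        self.tissues = {normalize_key(*k): set(v) for k, v in self.tissues.items()}
        self.scores = {normalize_key(*k): float(v) for k, v in self.scores.items()}
        self.genes = {normalize_key(*k): v for k, v in self.genes.items()}
        bad = [k for k, s in self.scores.items() if not 0.0 <= s <= 1.0]
        if bad:
            raise ValueError(f"pathogenicity scores outside [0, 1] for keys {bad[:3]}")
        # annotation keys are members by construction
        self.keys |= set(self.tissues) | set(self.scores) | set(self.genes)

    def __contains__(self, key) -> bool:
        return normalize_key(*key) in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in CALL_COLUMNS})


def _check_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    return calls


def read_cell_vcfs(paths, cell_ids=None) -> pd.DataFrame:
    """Read per-cell VCFs into one long call table.

    ``paths`` maps cell_id -> VCF path, or is an iterable of paths (then
    ``cell_ids`` supplies the matching ids, defaulting to file stems).
    Multi-allelic records are split into one call per alternate allele;
    depths come from the first sample's AD/DP FORMAT fields when present and
    are NaN otherwise.
    """
    from cyvcf2 import VCF

    if isinstance(paths, dict):
        items = list(paths.items())
    else:
        paths = list(paths)
        if cell_ids is None:
            import os

            cell_ids = [os.path.splitext(os.path.basename(str(p)))[0] for p in paths]
        items = list(zip(cell_ids, paths))
    rows = []
    for cell_id, path in items:
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
            raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
        def fmt(rec, tag):
            try:  # cyvcf2 raises KeyError when the tag is absent from the header
                return rec.format(tag)
            except KeyError:
                return None

        for rec in vcf:
            ad = fmt(rec, "AD")
            dp = fmt(rec, "DP")
            total = float(dp[0][0]) if dp is not None else np.nan
            for i, alt in enumerate(rec.ALT):
                alt_depth = float(ad[0][i + 1]) if ad is not None else np.nan
                rows.append(
                    (cell_id, rec.CHROM, rec.POS, rec.REF, alt, alt_depth, total)
                )
        vcf.close()
    if not rows:
        return empty_calls()
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


def filter_dbsnp(calls: pd.DataFrame, dbsnp: VariantCatalog) -> pd.DataFrame:
    """Remove calls whose key appears in the population catalog."""
    _check_calls(calls)
    if calls.empty:
        return calls.copy()
    keep = ~calls_to_keys(calls).isin(dbsnp.keys)
    return calls.loc[keep].reset_index(drop=True)


def subtract_germline(
    calls: pd.DataFrame,
    germline: dict[str, VariantCatalog],
    ann: pd.DataFrame,
) -> pd.DataFrame:
    """Remove each patient's germline variants from that patient's cells.

    Patients absent from ``germline`` are passed through unchanged with a
    logged notice (matching cohorts where blood was unavailable for some
    patients).
    """
    _check_calls(calls)
    if calls.empty:
        return calls.copy()
    patient_of = dict(zip(ann["cell_id"], ann["patient"]))
    unknown = set(calls["cell_id"]) - set(patient_of)
    if unknown:
        raise ValueError(f"cells without patient mapping: {sorted(unknown)[:5]}")
    patients = calls["cell_id"].map(patient_of)
    no_profile = set(patients) - set(germline)
    for p in sorted(no_profile):
        logger.info("germline subtraction omitted for patient %s (no germline profile)", p)
    keys = calls_to_keys(calls)
    keep = [
        p not in germline or k not in germline[p].keys
        for p, k in zip(patients, keys)
    ]
    return calls.loc[keep].reset_index(drop=True)


def filter_pathogenicity(
    calls: pd.DataFrame, scores: VariantCatalog, threshold: float = 0.7
) -> pd.DataFrame:
    """Keep calls with pathogenicity score strictly above ``threshold``.

    A score of exactly ``threshold`` is removed, as are calls with no score.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    _check_calls(calls)
    if calls.empty:
        return calls.copy()
    keys = calls_to_keys(calls)
    keep = [scores.scores.get(k, -1.0) > threshold for k in keys]
    return calls.loc[keep].reset_index(drop=True)


def filter_tissue(
    calls: pd.DataFrame, cosmic: VariantCatalog, tissue: str = "Lung"
) -> pd.DataFrame:
    """Keep calls cataloged with the given tissue label."""
    _check_calls(calls)
    if calls.empty:
        return calls.copy()
    keys = calls_to_keys(calls)
    keep = [tissue in cosmic.tissues.get(k, set()) for k in keys]
    return calls.loc[keep].reset_index(drop=True)


def run_filter_chain(
    calls: pd.DataFrame,
    dbsnp: VariantCatalog,
    germline: dict[str, VariantCatalog],
    pathogenicity: VariantCatalog,
    ann: pd.DataFrame,
    cosmic: VariantCatalog,
    threshold: float = 0.7,
    tissue: str = "Lung",
) -> pd.DataFrame:
    """dbSNP -> germline -> pathogenicity(> threshold) -> tissue, in order."""
    out = filter_dbsnp(calls, dbsnp)
    out = subtract_germline(out, germline, ann)
    out = filter_pathogenicity(out, pathogenicity, threshold=threshold)
    return filter_tissue(out, cosmic, tissue=tissue)


def aggregate_sample_gene(
    calls: pd.DataFrame,
    coverage: pd.DataFrame,
    gene_map: dict,
    ann: pd.DataFrame,
) -> pd.DataFrame:
    """Samples x genes mutant-read-ratio matrix.

    Entry = sum of alt depths over the sample's surviving calls in the gene,
    divided by the sample's total reads over that gene region (from
    ``coverage``, columns sample/gene/reads). Zero region coverage yields NC.
    Ratios exceeding 1 from depth bookkeeping are clipped with a warning.
    Calls mapping to no gene are dropped with a warning.
    """
    import warnings

    _check_calls(calls)
    for col in ("sample", "gene", "reads"):
        if col not in coverage.columns:
            raise ValueError(f"coverage table missing column {col!r}")
    gene_map = {normalize_key(*k): g for k, g in gene_map.items()}
    sample_of = dict(zip(ann["cell_id"], ann["sample"]))
    cov = coverage.pivot_table(index="sample", columns="gene", values="reads", aggfunc="sum")
    ratio = pd.DataFrame(0.0, index=cov.index, columns=cov.columns)
    if not calls.empty:
        keys = calls_to_keys(calls)
        genes = keys.map(gene_map)
        unmapped = genes.isna()
        if unmapped.any():
            warnings.warn(
                f"{int(unmapped.sum())} calls map to no gene; dropped", stacklevel=2
            )
        work = calls.loc[~unmapped].copy()
        work["gene"] = genes[~unmapped]
        work["sample"] = work["cell_id"].map(sample_of)
        alt = work.groupby(["sample", "gene"])["alt_depth"].sum()
        for (s, g), d in alt.items():
            if s in ratio.index and g in ratio.columns:
                ratio.loc[s, g] = d
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ratio / cov
    clipped = (out > 1).any().any()
    if clipped:
        warnings.warn("mutant depth exceeded region coverage; ratio clipped to 1", stacklevel=2)
    out = out.clip(upper=1.0)
    # zero coverage -> NC
    return out.mask(cov == 0, other=np.nan)


def binarize(ratio: pd.DataFrame, merge_nc: bool = False) -> pd.DataFrame:
    """Collapse a ratio matrix to present/absent, NC propagated.

    With ``merge_nc=True`` NC is displayed as absent (the figure-display
    convention); the default keeps NC distinct.
    """
    out = pd.DataFrame(NC, index=ratio.index, columns=ratio.columns, dtype=object)
    out = out.mask(ratio.notna() & (ratio > 0), "present")
    out = out.mask(ratio.notna() & (ratio == 0), "absent")
    if merge_nc:
        out = out.mask(out == NC, "absent")
    return out


def ercc_false_positive_rate(
    raw_calls: pd.DataFrame,
    spikein_contigs,
    coverage: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Per-cell false-positive mutation rate from ERCC spike-in contigs.

    Rate per cell = 100 x (raw calls on spike-in contigs) / (spike-in bases
    with coverage >= 1), i.e. a percentage per covered base; the cohort
    summary is the median over cells with nonzero covered bases. ``coverage``
    has columns cell_id / covered_bases.
    """
    spikein_contigs = set(spikein_contigs)
    if not spikein_contigs:
        raise ValueError("spike-in contig list is empty")
    _check_calls(raw_calls)
    cov = coverage.set_index("cell_id")["covered_bases"]
    cov = cov[cov > 0]
    if cov.empty:
        raise ValueError("no cell has ERCC coverage")
    if raw_calls.empty:
        n_ercc = pd.Series(0, index=cov.index)
    else:
        on_ercc = raw_calls[raw_calls["chrom"].isin(spikein_contigs)]
        n_ercc = on_ercc.groupby("cell_id").size().reindex(cov.index, fill_value=0)
    rates = (100.0 * n_ercc / cov).rename("fp_rate_pct")
    return rates, float(rates.median())


def mutation_burden_stratify(
    binary: pd.DataFrame, panel, threshold: int = 2
) -> pd.Series:
    """Label samples mutation-high/low by count of present panel mutations.

    High iff at least ``threshold`` panel entries are present; NC counts as
    absent.
    """
    panel = [g for g in panel if g in binary.columns]
    if not panel:
        raise ValueError("panel is empty or shares no genes with the matrix")
    counts = (binary[panel] == "present").sum(axis=1)
    return pd.Series(
        np.where(counts >= threshold, "high", "low"), index=binary.index, name="burden"
    )


def merge_fusion_calls(
    summary: pd.DataFrame, fusion_table: pd.DataFrame, ann: pd.DataFrame
) -> pd.DataFrame:
    """Append fusion-presence flags to a per-sample summary.

    ``fusion_table`` rows are (cell_id, fusion, junction_reads) from an
    external fusion caller; no filtering is applied here. Rows referencing
    unknown cells are logged and skipped.
    """
    out = summary.copy()
    if fusion_table.empty:
        return out
    sample_of = dict(zip(ann["cell_id"], ann["sample"]))
    known = fusion_table["cell_id"].isin(sample_of)
    for cid in fusion_table.loc[~known, "cell_id"]:
        logger.warning("fusion row for unknown cell %s skipped", cid)
    work = fusion_table.loc[known].copy()
    work["sample"] = work["cell_id"].map(sample_of)
    for fusion, sub in work.groupby("fusion"):
        col = f"fusion_{fusion}"
        out[col] = out.index.isin(set(sub["sample"]))
    return out
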