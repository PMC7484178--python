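"""Generate the synthetic longitudinal cohort and summarize its structure.

Three patients sampled at treatment-naive (TN), residual-disease (RD) and
progressive-disease (PD) time points; tumor cells carry one implanted gain
(chr1, 150 genes, +0.5 log2) and one loss (chr4, 120 genes, -0.6 log2);
stromal fibroblast/endothelial cells serve as presumed-diploid reference
controls. Writes a per-sample summary to results/.
"""

import os

import pandas as pd

from scpersist.simulate import default_cohort_config, simulate_expression

SEED = 1
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    config = default_cohort_config(seed=SEED)
    matrix, ann, genes, truth = simulate_expression(config)
    print(f"cohort: {matrix.n_genes} genes ({matrix.spikein.sum()} spike-ins) "
          f"x {matrix.n_cells} cells")
    summary = (
        ann.groupby(["patient", "sample", "time_point"])
        .agg(n_cells=("cell_id", "size"), n_controls=("is_reference_control", "sum"))
        .reset_index()
    )
    per_cell = pd.DataFrame(
        {
            "sample": ann["sample"].to_numpy(),
            "reads": matrix.reads_per_cell(),
            "genes_detected": matrix.detected_genes_per_cell(),
        }
    )
    depth = per_cell.groupby("sample").median().rename(
        columns={"reads": "median_reads", "genes_detected": "median_genes"}
    )
    summary = summary.merge(depth, on="sample")
    os.makedirs(RESULTS, exist_ok=True)
    summary.to_csv(os.path.join(RESULTS, "cohort_summary.csv"), index=False)
    print(summary.to_string(index=False))
    n_tumor = sum(truth.malignant.values())
    print(f"\nground truth: {n_tumor} malignant / {matrix.n_cells - n_tumor} non-malignant cells")


if __name__ == "__main__":
    main()
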