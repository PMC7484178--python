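"""Variant filter cascade, mutation matrices, and false-positive estimation."""

import logging

import numpy as np
import pandas as pd
import pytest

from scpersist import io as io_mod
from scpersist.simulate import SimulationConfig, simulate_variants
from scpersist.variants import (
    NC,
    VariantCatalog,
    aggregate_sample_gene,
    binarize,
    calls_to_keys,
    empty_calls,
    ercc_false_positive_rate,
    filter_dbsnp,
    filter_pathogenicity,
    filter_tissue,
    merge_fusion_calls,
    mutation_burden_stratify,
    normalize_key,
    read_cell_vcfs,
    run_filter_chain,
    subtract_germline,
)

from conftest import toy_cells


def make_calls(keys, cell_id="P0_c0", alt_depth=3, total_depth=10):
    return pd.DataFrame(
        [
            (cell_id, c, p, r, a, alt_depth, total_depth)
            for c, p, r, a in keys
        ],
        columns=["cell_id", "chrom", "pos", "ref", "alt", "alt_depth", "total_depth"],
    )


KEYS = [
    ("chr1", 100, "A", "T"),
    ("chr1", 200, "C", "G"),
    ("chr2", 100, "G", "A"),
    ("chr2", 300, "T", "C"),
    ("chr3", 50, "A", "G"),
]


class TestKeyNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (("chr1", 100, "A", "T"), ("chr1", 100, "A", "T")),
            (("chr1", 100, "AT", "GT"), ("chr1", 100, "A", "G")),  # shared suffix
            (("chr1", 100, "CA", "CG"), ("chr1", 101, "A", "G")),  # shared prefix
            (("chr1", 100, "CAT", "CGT"), ("chr1", 101, "A", "G")),
            (("chr1", 100, "AC", "A"), ("chr1", 100, "AC", "A")),  # deletion kept anchored
        ],
    )
    def test_minimal_representation(self, raw, expected):
        assert normalize_key(*raw) == expected


class TestVcfRoundTrip:
    def test_generated_vcfs_reload_identically(self, tmp_path):
        cfg = SimulationConfig(
            seed=5,
            variant_plan={"dbsnp": 3, "somatic_pathogenic_lung": 2, "ercc_artifact": 1},
        )
        cells = toy_cells()
        sim = simulate_variants(cfg, cells)
        contigs = io_mod.contigs_for(cfg)
        paths = io_mod.write_cell_vcfs(sim.calls, tmp_path / "cells", contigs)
        reread = read_cell_vcfs(paths)
        orig = sim.calls.sort_values(["cell_id", "chrom", "pos"]).reset_index(drop=True)
        got = reread.sort_values(["cell_id", "chrom", "pos"]).reset_index(drop=True)
        assert set(calls_to_keys(got)) == set(calls_to_keys(orig))
        assert got["alt_depth"].astype(int).tolist() == orig["alt_depth"].tolist()
        assert got["total_depth"].astype(int).tolist() == orig["total_depth"].tolist()

    def test_header_only_vcf_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.vcf"
        io_mod.write_vcf(make_calls([]), path, {"chr1": 1000}, sample="c0")
        assert read_cell_vcfs({"c0": path}).empty

    def test_multiallelic_record_splits(self, tmp_path):
        path = tmp_path / "ma.vcf"
        with open(path, "w") as fh:
            fh.write(
                "##fileformat=VCFv4.2\n"
                '##contig=<ID=chr1,length=1000>\n'
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                "chr1\t100\t.\tA\tT,G\t.\tPASS\t.\n"
            )
        calls = read_cell_vcfs({"c0": path})
        assert len(calls) == 2
        assert set(calls["alt"]) == {"T", "G"} and set(calls["pos"]) == {100}

    def test_catalog_vcf_round_trip(self, tmp_path):
        cat = VariantCatalog(keys=set(KEYS))
        path = tmp_path / "cat.vcf"
        io_mod.write_catalog_vcf(cat, path, {"chr1": 1000, "chr2": 1000, "chr3": 1000})
        assert io_mod.read_catalog_vcf(path).keys == cat.keys

    def test_catalog_tsv_round_trips(self, tmp_path):
        cosmic = VariantCatalog(
            tissues={KEYS[0]: {"Lung", "Breast"}, KEYS[1]: {"Skin"}},
            genes={KEYS[0]: "EGFR"},
        )
        io_mod.write_cosmic_tsv(cosmic, tmp_path / "c.tsv")
        back = io_mod.read_cosmic_tsv(tmp_path / "c.tsv")
        assert back.tissues == cosmic.tissues and back.genes == cosmic.genes
        scores = VariantCatalog(scores={KEYS[0]: 0.9, KEYS[1]: 0.3})
        io_mod.write_scores_tsv(scores, tmp_path / "s.tsv")
        assert io_mod.read_scores_tsv(tmp_path / "s.tsv").scores == pytest.approx(scores.scores)


class TestFilters:
    def test_dbsnp_empty_catalog_is_identity(self):
        calls = make_calls(KEYS)
        out = filter_dbsnp(calls, VariantCatalog())
        pd.testing.assert_frame_equal(out, calls)

    def test_dbsnp_removes_only_cataloged(self):
        calls = make_calls(KEYS)
        out = filter_dbsnp(calls, VariantCatalog(keys={KEYS[0], KEYS[2]}))
        assert len(out) == 3
        assert set(calls_to_keys(out)) == {KEYS[1], KEYS[3], KEYS[4]}

    def test_dbsnp_all_cataloged_empties(self):
        assert filter_dbsnp(make_calls(KEYS), VariantCatalog(keys=set(KEYS))).empty

    def test_germline_scoped_to_own_patient(self):
        ann = toy_cells()
        calls = pd.concat(
            [make_calls([KEYS[0]], cell_id="P0_c0"), make_calls([KEYS[0]], cell_id="P1_c0")]
        ).reset_index(drop=True)
        out = subtract_germline(calls, {"P0": VariantCatalog(keys={KEYS[0]})}, ann)
        assert out["cell_id"].tolist() == ["P1_c0"]

    def test_germline_missing_profile_passthrough_with_notice(self, caplog):
        ann = toy_cells()
        calls = make_calls([KEYS[0]], cell_id="P2_c0")
        with caplog.at_level(logging.INFO, logger="scpersist.variants"):
            out = subtract_germline(calls, {"P0": VariantCatalog(keys={KEYS[0]})}, ann)
        assert len(out) == 1
        assert any("omitted" in rec.message for rec in caplog.records)

    def test_germline_unmapped_cell_is_error(self):
        with pytest.raises(ValueError, match="patient"):
            subtract_germline(make_calls([KEYS[0]], cell_id="mystery"), {}, toy_cells())

    def test_pathogenicity_strict_threshold(self):
        calls = make_calls(KEYS[:4])
        scores = VariantCatalog(scores={KEYS[0]: 0.9, KEYS[1]: 0.7, KEYS[2]: 0.5})
        out = filter_pathogenicity(calls, scores)  # KEYS[3] unscored
        assert set(calls_to_keys(out)) == {KEYS[0]}

    def test_pathogenicity_keeps_score_one(self):
        out = filter_pathogenicity(make_calls([KEYS[0]]), VariantCatalog(scores={KEYS[0]: 1.0}))
        assert len(out) == 1

    def test_tissue_membership(self):
        cosmic = VariantCatalog(
            tissues={KEYS[0]: {"Lung", "Breast"}, KEYS[1]: {"Breast"}}
        )
        out = filter_tissue(make_calls(KEYS[:3]), cosmic)
        assert set(calls_to_keys(out)) == {KEYS[0]}

    def test_tissue_empty_catalog_empties(self):
        assert filter_tissue(make_calls(KEYS), VariantCatalog()).empty

    def test_filters_shrink_and_commute(self):
        """Each filter returns a subset; the set-membership filters commute."""
        cfg = SimulationConfig(
            seed=21,
            variant_plan={
                "dbsnp": 3,
                "germline": 3,
                "somatic_pathogenic_lung": 3,
                "somatic_benign": 2,
                "somatic_nonlung": 2,
            },
        )
        ann = toy_cells()
        sim = simulate_variants(cfg, ann)
        steps = {
            "d": lambda c: filter_dbsnp(c, sim.dbsnp),
            "g": lambda c: subtract_germline(c, sim.germline, ann),
            "p": lambda c: filter_pathogenicity(c, sim.pathogenicity),
            "t": lambda c: filter_tissue(c, sim.cosmic),
        }
        from itertools import permutations

        results = []
        for order in permutations("dgpt"):
            out = sim.calls
            for s in order:
                nxt = steps[s](out)
                assert set(calls_to_keys(nxt)) <= set(calls_to_keys(out)) or nxt.empty
                out = nxt
            results.append(frozenset(calls_to_keys(out)) if not out.empty else frozenset())
        assert len(set(results)) == 1

    def test_chain_recovers_exactly_the_pathogenic_lung_set(self):
        cfg = SimulationConfig(
            seed=33,
            variant_plan={
                "dbsnp": 4,
                "germline": 2,
                "somatic_pathogenic_lung": 2,
                "somatic_benign": 2,
                "somatic_nonlung": 1,
                "ercc_artifact": 2,
            },
        )
        ann = toy_cells()
        sim = simulate_variants(cfg, ann)
        kept = run_filter_chain(
            sim.calls, sim.dbsnp, sim.germline, sim.pathogenicity, ann, sim.cosmic
        )
        assert set(calls_to_keys(kept)) == sim.truth.keys_of("somatic_pathogenic_lung")

    def test_artifact_only_plan_yields_positive_fp_rate_and_empty_chain(self):
        cfg = SimulationConfig(seed=8, variant_plan={"ercc_artifact": 5})
        ann = toy_cells()
        sim = simulate_variants(cfg, ann)
        kept = run_filter_chain(
            sim.calls, sim.dbsnp, sim.germline, sim.pathogenicity, ann, sim.cosmic
        )
        assert kept.empty
        contigs = [c for c in sim.calls["chrom"].unique()]
        _, median_rate = ercc_false_positive_rate(sim.calls, contigs, sim.ercc_coverage)
        assert median_rate > 0


class TestMutationMatrix:
    ANN = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "patient": ["P0", "P0", "P1"],
            "sample": ["s1", "s1", "s2"],
        }
    )
    GENE_MAP = {KEYS[0]: "EGFR", KEYS[1]: "TP53"}
    COVERAGE = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s2", "s2"],
            "gene": ["EGFR", "TP53", "EGFR", "TP53"],
            "reads": [10, 8, 0, 6],
        }
    )

    def test_ratio_arithmetic_and_nc(self):
        calls = make_calls([KEYS[0]], cell_id="c1", alt_depth=3)
        m = aggregate_sample_gene(calls, self.COVERAGE, self.GENE_MAP, self.ANN)
        assert m.loc["s1", "EGFR"] == pytest.approx(0.3)
        assert m.loc["s1", "TP53"] == 0.0
        assert np.isnan(m.loc["s2", "EGFR"])  # zero coverage -> NC

    def test_all_reads_mutant_is_one(self):
        calls = make_calls([KEYS[1]], cell_id="c3", alt_depth=6)
        m = aggregate_sample_gene(calls, self.COVERAGE, self.GENE_MAP, self.ANN)
        assert m.loc["s2", "TP53"] == 1.0

    def test_excess_depth_clipped_with_warning(self):
        calls = make_calls([KEYS[0]], cell_id="c1", alt_depth=25)
        with pytest.warns(UserWarning, match="clipped"):
            m = aggregate_sample_gene(calls, self.COVERAGE, self.GENE_MAP, self.ANN)
        assert m.loc["s1", "EGFR"] == 1.0

    def test_unmapped_call_dropped_with_warning(self):
        calls = make_calls([KEYS[4]], cell_id="c1")
        with pytest.warns(UserWarning, match="no gene"):
            m = aggregate_sample_gene(calls, self.COVERAGE, self.GENE_MAP, self.ANN)
        assert (m.fillna(-1) != 0).sum().sum() == 1  # only the NC cell differs from 0

    def test_binarize_states(self):
        calls = make_calls([KEYS[0]], cell_id="c1", alt_depth=3)
        m = aggregate_sample_gene(calls, self.COVERAGE, self.GENE_MAP, self.ANN)
        b = binarize(m)
        assert b.loc["s1", "EGFR"] == "present"
        assert b.loc["s1", "TP53"] == "absent"
        assert b.loc["s2", "EGFR"] == NC
        merged = binarize(m, merge_nc=True)
        assert merged.loc["s2", "EGFR"] == "absent"

    def test_binarization_idempotent_under_rebinarize(self):
        calls = make_calls([KEYS[0]], cell_id="c1", alt_depth=3)
        m = aggregate_sample_gene(calls, self.COVERAGE, self.GENE_MAP, self.ANN)
        b = binarize(m)
        as_ratio = b.apply(lambda col: col.map({"present": 1.0, "absent": 0.0, NC: np.nan}))
        pd.testing.assert_frame_equal(binarize(as_ratio), b)


class TestErccRate:
    def cov(self, cells_bases):
        return pd.DataFrame(
            {"cell_id": list(cells_bases), "covered_bases": list(cells_bases.values())}
        )

    def test_zero_calls_zero_rate(self):
        rates, med = ercc_false_positive_rate(empty_calls(), ["ERCC-1"], self.cov({"c1": 5000}))
        assert rates["c1"] == 0 and med == 0

    def test_rate_arithmetic(self):
        calls = make_calls(
            [("ERCC-1", 10, "A", "T"), ("ERCC-1", 20, "C", "G")], cell_id="c1"
        )
        rates, _ = ercc_false_positive_rate(calls, ["ERCC-1"], self.cov({"c1": 10_000}))
        assert rates["c1"] == pytest.approx(0.02)

    def test_cohort_median(self):
        calls = pd.concat(
            [
                make_calls([("ERCC-1", 10, "A", "T")], cell_id="c2"),
                make_calls([("ERCC-1", 10, "A", "T"), ("ERCC-1", 30, "A", "T")], cell_id="c3"),
            ]
        ).reset_index(drop=True)
        _, med = ercc_false_positive_rate(
            calls, ["ERCC-1"], self.cov({"c1": 10_000, "c2": 5_000, "c3": 5_000})
        )
        assert med == pytest.approx(0.02)

    def test_no_coverage_is_error(self):
        with pytest.raises(ValueError, match="coverage"):
            ercc_false_positive_rate(empty_calls(), ["ERCC-1"], self.cov({"c1": 0}))


class TestBurdenAndFusions:
    BINARY = pd.DataFrame(
        {
            "EGFR": ["present", "present", "absent"],
            "TP53": ["present", NC, "absent"],
            "KRAS": ["absent", "absent", "absent"],
        },
        index=["s1", "s2", "s3"],
    )

    def test_two_mutations_is_high(self):
        labels = mutation_burden_stratify(self.BINARY, ["EGFR", "TP53", "KRAS"])
        assert labels["s1"] == "high"

    def test_one_mutation_is_low_and_nc_counts_absent(self):
        labels = mutation_burden_stratify(self.BINARY, ["EGFR", "TP53", "KRAS"])
        assert labels["s2"] == "low"  # NC not counted as present

    def test_zero_mutations_is_low(self):
        labels = mutation_burden_stratify(self.BINARY, ["EGFR", "TP53", "KRAS"])
        assert labels["s3"] == "low"

    def test_empty_panel_is_error(self):
        with pytest.raises(ValueError, match="panel"):
            mutation_burden_stratify(self.BINARY, ["BRAF"])

    def test_fusion_merge(self, caplog):
        ann = pd.DataFrame({"cell_id": ["c1", "c2"], "sample": ["s1", "s2"],
                            "patient": ["P0", "P0"]})
        summary = pd.DataFrame({"n_mutations": [2, 0]}, index=["s1", "s2"])
        fusions = pd.DataFrame(
            {
                "cell_id": ["c1", "ghost"],
                "fusion": ["EML4-ALK", "EML4-ALK"],
                "junction_reads": [7, 3],
            }
        )
        with caplog.at_level(logging.WARNING, logger="scpersist.variants"):
            out = merge_fusion_calls(summary, fusions, ann)
        assert out.loc["s1", "fusion_EML4-ALK"] and not out.loc["s2", "fusion_EML4-ALK"]
        assert any("ghost" in rec.message for rec in caplog.records)

    def test_empty_fusion_table_unchanged(self):
        summary = pd.DataFrame({"n_mutations": [1]}, index=["s1"])
        out = merge_fusion_calls(
            summary, pd.DataFrame(columns=["cell_id", "fusion", "junction_reads"]),
            pd.DataFrame({"cell_id": [], "sample": [], "patient": []}),
        )
        pd.testing.assert_frame_equal(out, summary)
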