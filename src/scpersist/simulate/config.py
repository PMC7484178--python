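"""Simulation configuration: the study conditions every generator draws from.

A single :class:`SimulationConfig` describes the whole synthetic cohort —
chromosome layout, cell groups with patient/sample/time-point structure,
implanted CNV segments, the variant plan by category, coverage, the survival
cohort and the composition proportions — so that one seeded config
reproduces every pipeline input byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

VARIANT_CATEGORIES = (
    "dbsnp",
    "germline",
    "somatic_pathogenic_lung",
    "somatic_benign",
    "somatic_nonlung",
    "ercc_artifact",
)

#: pathogenicity-score sampling interval per category; pathogenic categories
#: sit strictly above the 0.7 reporting threshold, benign strictly below
DEFAULT_PATHOGENICITY_RANGES = {
    "somatic_pathogenic_lung": (0.75, 0.99),
    "somatic_benign": (0.05, 0.65),
    "somatic_nonlung": (0.75, 0.99),
}


@dataclass(frozen=True)
class CellGroup:
    label: str
    patient: str
    sample: str
    time_point: str
    cell_type: str
    n_cells: int
    is_control: bool = False
    is_tumor: bool = False


@dataclass(frozen=True)
class CnvSegment:
    chromosome: str
    start_gene: int  # 0-based index within the chromosome's gene order
    length: int  # number of genes
    log2_effect: float


@dataclass(frozen=True)
class ExpressionShift:
    """A treatment-time-point expression program: genes [start_gene,
    start_gene + length) gain 2^log2_effect mean expression in (tumor) cells
    of the given time point. Gene indices are global (annotation order)."""

    time_point: str
    start_gene: int
    length: int
    log2_effect: float
    tumor_only: bool = True


@dataclass(frozen=True)
class SurvivalPlan:
    n_subjects: int = 510
    baseline_hazard: float = 0.02  # events per month
    quartile_multipliers: tuple = (1.0, 1.2, 1.5, 2.0)
    censoring_rate: float = 0.3


@dataclass(frozen=True)
class CompositionPlan:
    # proportions[time_point][cell_type]; each time point sums to 1
    proportions: dict = field(default_factory=dict)
    group_totals: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1200
    chromosomes: tuple = (("chr1", 200), ("chr2", 200), ("chr3", 200),
                          ("chr4", 200), ("chr5", 200), ("chr6", 200))
    cell_groups: tuple = ()
    cnv_segments: tuple = ()
    expression_shifts: tuple = ()
    baseline_mean: float = 1.0
    dropout_rate: float = 0.1
    dropout_scale: float = 10.0  # expected counts at which dropout has decayed ~e-fold
    library_size_range: tuple = (150_000, 600_000)
    n_ercc: int = 20
    nb_dispersion: float = 0.3
    count_law: str = "nb"  # "nb" or "poisson"
    cell_type_sigma: float = 0.15
    variant_plan: dict = field(default_factory=dict)
    pathogenicity_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PATHOGENICITY_RANGES))
    coverage_depth: float = 30.0
    variant_carrier_rate: float = 0.6
    survival_plan: SurvivalPlan = field(default_factory=SurvivalPlan)
    composition_plan: CompositionPlan = field(default_factory=CompositionPlan)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes != sum(n for _, n in self.chromosomes):
            raise ValueError("n_genes must equal the summed chromosome gene counts")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.dropout_scale <= 0:
            raise ValueError("dropout_scale must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.count_law not in ("nb", "poisson"):
            raise ValueError("count_law must be 'nb' or 'poisson'")
        if self.library_size_range is not None:
            lo, hi = self.library_size_range
            if not (0 < lo <= hi):
                raise ValueError("library_size_range must satisfy 0 < min <= max")
        labels = [g.label for g in self.cell_groups]
        if len(set(labels)) != len(labels):
            raise ValueError("cell group labels must be unique")
        sizes = {c: n for c, n in self.chromosomes}
        for seg in self.cnv_segments:
            if seg.chromosome not in sizes:
                raise ValueError(f"CNV segment on unknown chromosome {seg.chromosome!r}")
            if seg.length < 1 or seg.start_gene < 0 or (
                seg.start_gene + seg.length > sizes[seg.chromosome]
            ):
                raise ValueError(
                    f"CNV segment {seg} lies outside chromosome {seg.chromosome!r} "
                    f"({sizes[seg.chromosome]} genes)"
                )
        for sh in self.expression_shifts:
            if sh.start_gene < 0 or sh.length < 1 or sh.start_gene + sh.length > self.n_genes:
                raise ValueError(f"expression shift {sh} lies outside the gene range")
        bad = set(self.variant_plan) - set(VARIANT_CATEGORIES)
        if bad:
            raise ValueError(f"unknown variant categories: {sorted(bad)}")
        if any(v < 0 for v in self.variant_plan.values()):
            raise ValueError("variant_plan counts must be non-negative")
        for cat, (lo, hi) in self.pathogenicity_ranges.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"pathogenicity range for {cat!r} must lie within [0, 1]")
        sp = self.survival_plan
        if sp.n_subjects < 8:
            raise ValueError("survival plan needs at least 8 subjects")
        if any(m <= 0 for m in sp.quartile_multipliers):
            raise ValueError("hazard multipliers must be positive")
        if not 0.0 <= sp.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1); >= 1 leaves no events")
        for tp, props in self.composition_plan.proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition proportions for {tp!r} sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError("composition proportions must be non-negative")

    # ------------------------------------------------------------------
    def rng(self, stream: int) -> np.random.Generator:
        """Per-submodule random stream.

        One global seed expands into independent child streams (expression=0,
        variants=1, survival=2, composition=3) so adding a generator never
        shifts the outputs of another.
        """
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])

    def replace(self, **kwargs) -> "SimulationConfig":
        data = {**self.__dict__, **kwargs}
        return SimulationConfig(**data)

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "cell_groups" in raw:
            raw["cell_groups"] = tuple(CellGroup(**g) for g in raw["cell_groups"])
        if "cnv_segments" in raw:
            raw["cnv_segments"] = tuple(CnvSegment(**s) for s in raw["cnv_segments"])
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple((c, int(n)) for c, n in raw["chromosomes"])
        if "library_size_range" in raw and raw["library_size_range"] is not None:
            raw["library_size_range"] = tuple(raw["library_size_range"])
        if "survival_plan" in raw and isinstance(raw["survival_plan"], dict):
            sp = dict(raw["survival_plan"])
            if "quartile_multipliers" in sp:
                sp["quartile_multipliers"] = tuple(sp["quartile_multipliers"])
            raw["survival_plan"] = SurvivalPlan(**sp)
        if "composition_plan" in raw and isinstance(raw["composition_plan"], dict):
            raw["composition_plan"] = CompositionPlan(**raw["composition_plan"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ----------------------------------------------------------------------
def default_cohort_config(seed: int = 0) -> SimulationConfig:
    """A small longitudinal cohort: 3 patients x TN/RD/PD with tumor cells
    carrying one gained and one lost segment, normal epithelium, and stromal
    reference controls."""
    groups = []
    for p in ("P1", "P2", "P3"):
        for tp in ("TN", "RD", "PD"):
            groups.append(CellGroup(f"{p}_{tp}_tumor", p, f"{p}_{tp}", tp, "epithelial", 40, is_tumor=True))
            groups.append(CellGroup(f"{p}_{tp}_normal", p, f"{p}_{tp}", tp, "epithelial", 15))
    groups.append(CellGroup("ctrl_fibro", "P1", "P1_TN", "TN", "fibroblast", 15, is_control=True))
    groups.append(CellGroup("ctrl_endo", "P1", "P1_TN", "TN", "endothelial", 15, is_control=True))
    comp = CompositionPlan(
        proportions={
            "TN": {"T cell": 0.35, "Macrophage": 0.25, "B cell": 0.15, "NK": 0.15, "Dendritic": 0.10},
            "RD": {"T cell": 0.45, "Macrophage": 0.15, "B cell": 0.15, "NK": 0.15, "Dendritic": 0.10},
            "PD": {"T cell": 0.25, "Macrophage": 0.40, "B cell": 0.12, "NK": 0.13, "Dendritic": 0.10},
        },
        group_totals={"TN": 300, "RD": 300, "PD": 300},
    )
    return SimulationConfig(
        seed=seed,
        cell_groups=tuple(groups),
        cnv_segments=(
            CnvSegment("chr1", 20, 150, 0.5),
            CnvSegment("chr4", 40, 120, -0.6),
        ),
        variant_plan={
            "dbsnp": 5,
            "germline": 4,
            "somatic_pathogenic_lung": 3,
            "somatic_benign": 3,
            "somatic_nonlung": 2,
            "ercc_artifact": 2,
        },
        composition_plan=comp,
    )


def cnv_benchmark_config(seed: int = 0) -> SimulationConfig:
    """The CNV-recovery condition: 100 tumor cells with a single +0.5 log2
    gain over 150 genes, 100 normal epithelial cells, 40 stromal controls."""
    groups = (
        CellGroup("tumor", "P1", "P1_TN", "TN", "epithelial", 100, is_tumor=True),
        CellGroup("normal", "P1", "P1_TN", "TN", "epithelial", 100),
        CellGroup("ctrl_fibro", "P1", "P1_TN", "TN", "fibroblast", 20, is_control=True),
        CellGroup("ctrl_endo", "P1", "P1_TN", "TN", "endothelial", 20, is_control=True),
    )
    return SimulationConfig(
        seed=seed,
        cell_groups=groups,
        cnv_segments=(CnvSegment("chr1", 20, 150, 0.5),),
    )
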