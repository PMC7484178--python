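# Methods

This note records the models implemented in `scpersist`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Quality control and normalization

A cell is kept iff it has ≥ 500 detected endogenous genes **and** ≥ 50,000
endogenous reads (both conditions as floors; "detected" means count > 0).
ERCC spike-ins are technical controls added to the lysis buffer, so they are
excluded from both tallies and from the normalization denominator —
including them would let spike-in content rescue shallow cells and distort
per-cell totals. Whole samples with fewer than 10 post-QC cells are dropped
(a 10-cell sample survives). Normalization is
`ln(1 + 10^4 · c / C)` with `C` the cell's endogenous total; spike-in rows
are normalized by the same total so values stay comparable within a cell.

## Expression-inferred CNV and malignancy calling

Large copy-number changes shift the average expression of the genes they
span. The profile construction is:

1. order expressed genes by (chromosome, start);
2. center each gene on its mean over the reference cells (spiked-in
   fibroblasts/endothelial cells, presumed diploid) and cap at ±3 — the
   standard relative-expression construction, which makes reference cells
   average exactly zero per gene;
3. smooth with a moving average anchored at every gene position `i`,
   covering genes `[i − w/2, i + w/2]` with `w = 100`, truncated at
   chromosome boundaries (no padding; a chromosome shorter than the window
   contributes its overall mean at every position). Truncation is the
   simplest rule that keeps windows strictly within a chromosome.

The per-cell **CNV score** is the mean of squared window values: zero iff
the profile is flat, growing with both the breadth and amplitude of
deviation. This is the standard signal-extent (second-moment) statistic; a
different score would reorder cells only if their profiles differ in shape
but not energy.

Cells are clustered by Ward linkage on the Euclidean distance between
window profiles. Raw window vectors rather than a correlation distance are
used because the profile amplitude — not just its shape — is the malignancy
signal. The dendrogram is cut by scanning k = 2, 3, … and taking the
smallest k at which all but at most `tolerance` (default 1, formalizing a
single misassigned control) of the spiked controls co-occur in one cluster;
cells in that control cluster are non-tumor, the rest tumor. Because
clusters only merge as k decreases, the scan usually terminates at k = 2
when the leading split already separates aberrant cells from the
diploid mass; larger k is reached only when an early split divides the
controls. Per-cell median subtraction after smoothing is available as an
option but off by default.

## Somatic variant filtering

Variant calls from single-cell transcriptomes are dominated by population
polymorphism, patient germline, and artifact. The cascade retains a call
iff it survives all of: (1) key not in the dbSNP-like catalog; (2) key not
in the call's own patient's germline profile (patients without a profile
pass through with a logged notice); (3) pathogenicity score strictly
greater than 0.7 — a score of exactly 0.7 is excluded, and **unscored calls
are removed** (only calls positively predicted pathogenic are reportable);
(4) key cataloged with the target tissue ("Lung"). All keys are normalized
to a left-aligned minimal representation before any membership test, since
representation drift between callers and catalogs is the dominant source of
false mismatches. The three catalog filters are set intersections and
commute; germline subtraction commutes too once the patient mapping is
fixed.

The mutation matrix entry for (sample, gene) is the summed alternate-read
depth of the sample's surviving calls in the gene divided by the sample's
total reads over the region; zero region coverage yields **NC**, a third
state deliberately distinct from ratio 0 ("covered but wild-type"). The
binary companion maps ratio > 0 to present and 0 to absent, propagating NC;
a display mode merges NC into absent for figure-style rendering. Burden
stratification counts present panel entries (NC counts as absent, the
conservative choice) and labels a sample high iff the count is ≥ 2.

The ERCC false-positive rate per cell is
`100 × (calls on spike-in contigs) / (spike-in bases with coverage ≥ 1)` —
a percentage per covered base — summarized as the median over cells with
nonzero covered bases. Any call on a spike-in contig is false by
construction, since the spike-in sequences are synthetic and invariant.

## Composition statistics

Patient occupancy of a cluster is the largest single-patient share of its
cells; values near 1 flag patient-private (typically malignant) clusters.
Relative frequencies get **Wilson score intervals** (truncated to [0, 1]):
unlike the Wald interval, Wilson behaves correctly at 0 and 1 and holds its
coverage at moderate n; a `method="wald"` flag reproduces the plain normal
interval where needed, and `simultaneous=True` Bonferroni-adjusts the
per-category level so the intervals hold jointly across categories.
Independence across time points is Pearson's chi-square without continuity
correction; zero expected counts are an error (merge sparse categories).
Per-cell-type significance is obtained by testing each type against the
rest (a 2 × time-points table per type), matching per-type annotation of
fraction-change panels.

The immunoreactivity score is intensity (0–3) × percent-positivity
coefficient: 0 at 0 %, 1 below 10 %, 2 from 10–50 %, 3 from 51–80 %,
4 above 80 %. The stated bins leave (50, 51) unassigned; values there map
to coefficient 3 so the bins stay contiguous. The RT-PCR fold change is
`2^(Ct_control − Ct_treated)`; housekeeping normalization is assumed
already applied to the inputs.

## Signature scoring

A signature score is the unweighted mean of log-normalized expression over
the signature genes present in the matrix (missing genes are counted and
reported, never imputed). No control-gene-set background correction is
applied by default — the same plain mean is used per cell and per sample,
so within-cohort and external-cohort scores are directly comparable.
Pairwise time-point comparisons use the two-sided Wilcoxon rank-sum test
(exact when samples are small and untied, asymptotic otherwise) with Holm
adjustment across the pairs; raw p-values are reported alongside. Dot-plot
statistics z-score each gene across all cells before group means
(zero-variance genes are defined as z = 0) and report the fraction of cells
with nonzero expression. The patient-support filter keeps a
differentially-expressed gene only if, within the gene's time-point group,
at least the threshold number of distinct patients contribute a cell
expressing it — guarding against single-patient effects masquerading as
treatment signal.

## Survival analysis

Quartile assignment sorts subjects ascending (ties broken by stable input
order) and assigns rank `i` (0-based) to quartile `⌊4·i/n⌋`. This rule is
pinned by the printed cohort split: for n = 510 it uniquely yields group
sizes (128, 127, 128, 127) with Q1 lowest, whereas quantile-threshold
rules give (127, 128, 127, 128). Kaplan–Meier estimation, the k-sample
log-rank test and the Cox fit are delegated to lifelines; the Cox model
uses a single Q4-indicator covariate (so HR reads "high vs low") with
Efron handling of tied event times, and errors explicitly when a group has
no events (monotone partial likelihood). The median split labels values
strictly above the median high; ties at the median go low, so an
all-constant vector is all-low rather than arbitrarily split.
Total-macrophage and total-T/NK fractions are fixed column-set row sums
over CIBERSORT LM22 population names; missing columns are treated as zero
with a warning rather than an error, since deconvolution tables routinely
omit empty populations.

## Synthetic-data generators

One `SimulationConfig` with one seed reproduces every input byte-for-byte;
the global seed expands into independent child streams per generator
(expression, variants, survival, composition), so adding draws to one
generator never shifts another's output.

**Expression.** Per-gene baseline weights are gamma-distributed
(shape 1, scale `baseline_mean`); each cell type gets a log-normal
per-gene offset (σ = 0.15) drawn once and shared by its cells, giving
cell-type-structured counts; per-cell library sizes are uniform on
150,000–600,000 reads (plate-based libraries are deep; the true library
distribution is a free parameter and this range keeps every honest cell
above the 50,000-read QC floor). Expected counts are the cell's library
size times its normalized weights; tumor cells multiply segment genes by
`2^effect` for each implanted CNV segment, and time-point expression
programs (`ExpressionShift`) do the same for signature-style gene blocks.
Counts are negative binomial with dispersion 0.3 by default (variance
μ + 0.3 μ²) — downstream smoothing and classification must tolerate
overdispersion, and 0.3 is a typical single-cell value; a Poisson option
exists. Dropout is expression-dependent zero-inflation: an entry is zeroed
with probability `rate^(1 + μ/scale)` (scale = 10 expected counts), i.e.
the configured rate for a barely-expressed gene, decaying geometrically
with expected counts. Plate-based dropout is depth-limited, so
well-expressed genes are essentially never lost; `rate = 1` still
degenerates to zeroing everything and `rate = 0` to no dropout. ERCC rows
are appended with log-uniform abundances scaled to 3 % of the library,
Poisson-distributed and exempt from dropout. Genes sit on a regular
coordinate grid (1 kb spans every 1.5 kb) along configured chromosomes.

**Variants.** Each planned variant draws a unique (chrom, pos, ref, alt)
key uniformly within a random gene (or spike-in contig for artifacts),
is assigned to one patient, and appears in a random subset of that
patient's cells (carrier rate 0.6, at least one cell). Categories determine
placement: dbsnp keys enter the population catalog; germline keys the
patient's germline profile; somatic categories get pathogenicity scores
sampled from per-category ranges (pathogenic 0.75–0.99, benign 0.05–0.65)
and COSMIC tissue labels ("Lung" for lung categories, another tissue
otherwise). By construction the filter cascade should return exactly the
`somatic_pathogenic_lung` key set — the end-to-end bookkeeping oracle.
Coverage tables are Poisson around `coverage_depth` per cell with the
summed alternate depths as a floor at variant-bearing genes, and a random
tenth of variant-free (sample, gene) pairs get zero coverage so the NC
state is exercised.

**Survival.** Covariates are standard normal; the subject's true covariate
quartile selects a hazard multiplier and event times are exponential with
rate baseline × multiplier (baseline 0.02/month ⇒ ~35-month median).
Censoring is independent exponential with rate `λ·c/(1−c)`, which makes the
expected censored fraction exactly `c` within every quartile; `c ≥ 1` is
rejected since no events could be observed.

**Composition.** One multinomial draw per time point at the configured
total (default 300 cells) from proportions that sum to 1.

**What the generators do not emulate:** read-level artifacts (no FASTQ,
alignment or UMI structure), doublets, ambient RNA, batch effects between
plates, gene-length or GC bias, linked CNV-expression dosage beyond the
mean shift, subclonal structure, and non-proportional hazards. Passing
tests therefore demonstrate correctness of the statistical machinery and
recoverability of implanted effects under realistic noise — not robustness
to every artifact of real tissue data.

## Benchmark problem sizes

The recovery and calibration benchmarks (shared by the test suite and
`scripts/acceptance.py`) use: 20 seeded CNV cohorts of 240 cells × 1,200
genes (100 tumor with a +0.5 log2 gain over 150 genes, 100 normal, 40
controls); 100 random variant plans of up to 4 variants per category over
18 cells; 500 null replicates for each type-I-error check (3 × 4
composition tables of 200 cells per group; 4 × 100-subject survival
cohorts with 20 % censoring); 2,000 binomial replicates at n = 50,
p ∈ {0.1, 0.5} for Wilson coverage; 100 replicates of 1,000-subject
cohorts for Cox CI coverage at a true hazard ratio of 2; and one
500-subject uncensored cohort for the KM median check. These sizes give
Monte-Carlo standard errors comfortably inside the acceptance margins
while keeping a full run under a minute.

## Known limitations

- The dendrogram-cut rule returns the *smallest* qualifying k; data whose
  first split divides the stromal controls will push k higher, and a
  control contaminated with true CNV signal can make the cut impossible at
  tolerance 0 (an explicit error suggests raising the tolerance).
- The CNV score is scale-dependent (mean square of smoothed log-ratios);
  scores are comparable within one profile construction, not across
  different window sizes or caps.
- Key normalization handles left-alignment and minimal representation but
  not reference-genome liftover or strand flips between catalogs.
- The Cox interface is the single-contrast Q1-vs-Q4 fit; multivariable
  adjustment and competing risks are out of scope.
- With heavy ties the rank-sum test falls back to the asymptotic
  approximation; exact enumeration is used only for small untied samples.
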