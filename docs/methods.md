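# Methods

This note documents the models, rules and numerical choices implemented in
`scolitis`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Cell QC

Cells are retained when they have at least `min_genes` (default 200) detected
genes **and** at most `max_mito_fraction` (default 0.20) of their UMIs on
genes whose names start with `MT-`. Both boundaries are inclusive for
retention: exactly 200 genes or exactly 20% mitochondrial content passes.
"Mitochondrial content" is a fraction of total UMI counts, not of detected
genes — the standard convention; the alternative reading is noted here rather
than asserted as universal. Cells with zero total counts have no defined
mitochondrial fraction and are always removed (tallied as low-gene). A cell
failing both rules is counted in both per-rule tallies, so the tallies can
sum to more than the number of removed cells.

Droplet calling is out of scope: the module consumes already-called barcodes
and records the upstream parameters (EmptyDrops-style, lower UMI bound 100,
FDR < 0.01) as provenance metadata only. Study-specific manual removals
(an overloaded library; clusters defined solely by mitochondrial genes) are
supported as an explicit barcode blacklist, not automated — they are curation
decisions, not reproducible rules.

## Compartment assignment

Expression is normalized to counts-per-10,000 and log1p-transformed. The
dataset is clustered at resolution 2 (the conventional high-resolution
setting for compartment separation) and each cluster scored per compartment
as the mean over the compartment's curated marker genes of the mean
normalized expression over the cluster's cells (cell mean first, then gene
mean). The curated sets are fixed colonic-mucosa markers: epithelial
(EPCAM, KRT8, KRT18), stromal (COL1A1/2, COL6A1/2, VWF, PLVAP, CDH5, S100B),
immune (CD52, CD2, CD3D/E/G, CD79A/B, CD14, CD16, CD68, CD83, CSF1R, FCER1G).
CD16 is not a current HGNC symbol and is matched to FCGR3A via an alias
table (logged); other missing markers are logged and skipped, but a
compartment with zero matched genes is an error.

Clusters are named by maximum score. Ties are broken by the fixed order
immune > epithelial > stromal with a logged warning; ties essentially never
occur on real data and signal degenerate input. Whether average expression
should be read from raw or normalized values is not uniquely determined by
convention; this implementation scores normalized values and documents the
choice rather than claiming fidelity to any particular upstream tool.

## Clustering backend and stability

The default backend mirrors the standard single-cell pipeline:
log-normalization, per-gene z-scaling clipped at ±10, PCA to 50 components
(fewer if the data are smaller), a k-nearest-neighbor graph (k = 20,
truncated with a warning when k ≥ n), shared-nearest-neighbor Jaccard
edge weights pruned below 1/15, and Leiden modularity optimization
(RB-configuration, 2 iterations) at the requested resolution. Everything is
deterministic given the seed. Note that the effective resolution scale is
backend-specific: on a 200-cell two-blob benchmark this backend recovers the
two blobs exactly at resolutions up to ~0.5 and begins splitting them at 1.0.

Stability evaluation clusters the full data once per resolution, then for
each of `n_iter` (default 20) iterations subsamples ⌊0.9·n⌋ cells without
replacement, reclusters with a fresh derived seed, and computes the adjusted
Rand index against the full-data labeling restricted to the subsample. The
derived seed is `master·1000003 + resolution_index·10007 + iteration`
(mod 2³¹−1): reproducible, distinct per cell of the grid, and independent of
how many resolutions are evaluated. The ARI is the Hubert–Arabie
chance-corrected form computed from the pair-counting contingency table;
when both partitions are trivial (all-singleton or single-block) the index
is defined as 1.

The selected resolution is the largest before the *median* ARI starts
decreasing, with a tolerance of 0.01 on "decreasing" because raw medians
jitter between adjacent resolutions and an exact-decrease rule would be
seed-sensitive. Medians (not means or visual inspection) are the documented
choice. The resolution grid is user-supplied (default 0.2–2.0 in steps of
0.2).

## Compositional analysis

Per-patient proportions are computed under a configurable denominator: all
cells of the (already compartment-restricted) table, the cell's parent
lineage, cycling cells only, or a custom set. Patients with an empty
denominator are emitted with a missing proportion and a flag, never silently
dropped. Enrichment stacks report, per cell type, each cohort's share of the
pooled cells (summing to 1) together with per-patient contribution fractions.
The IgG/IgA ratio divides IGHG-labeled by IGHA-labeled plasma-cell counts per
patient; with zero IGHA cells the ratio is reported missing and flagged
rather than pseudocounted, since it feeds plots, not models. Isotype labels
are consumed as given (from the cluster annotation), not recomputed from raw
transcripts. The Bayesian compositional model used for significance in the
motivating workflow (scCODA) is intentionally not re-implemented;
`sccoda_count_table` emits the layout it expects for external use.

## Pseudobulk differential expression

Raw counts are summed per (patient, cell type) in exact integer arithmetic;
groups with fewer than 5 cells are dropped. Columns are normalized to
counts-per-million and log2(x+1)-transformed. The built-in comparison engine
is the Wilcoxon–Mann–Whitney rank-sum test on patient-level log-CPM values:
exact null when min(n₁, n₂) ≤ 8 with no ties, tie-corrected normal
approximation otherwise; completely degenerate data (all values identical)
returns p = 1. The published GLM engines often used for this step
(limma-voom, edgeR) are deliberately not re-implemented — the pseudobulk
layout is exportable for them — because the rank-sum engine is
assumption-light and testable by enumeration; this substitution is the
module's main design decision. Log2 fold change is the difference of mean
log2-CPM between sides. BH adjustment runs over genes within one comparison
and cell type, matching per-panel significance reporting; a global family is
not used and the choice is documented. Cluster-marker detection reuses the
rank-sum test one-cluster-vs-rest at the single-cell level, with candidate
thresholds (log2FC ≥ 0.25, ≥ 10% expressing) reported as flags, not applied
destructively. A static cytokine/chemokine panel (GO "cytokine activity" /
"chemokine activity" snapshot, retrieved 2025-09) ships with the package
rather than being fetched live.

## TCR clonotype analysis

Contigs are filtered to productive AND high-confidence; per barcode the set
of retained CDR3 amino-acid sequences is the clonotype key, so identical
sets across a patient's libraries merge into one clonotype with pooled cells
and a new patient-level ID. Duplicate (barcode, chain, cdr3) rows are
deduplicated with a warning. Frequencies and Shannon diversity
(H = −Σ pᵢ ln pᵢ, natural log — the common default; no base is canonical)
are computed over per-clonotype cell counts of clonotype-bearing cells;
cells without a productive TCR are excluded from denominators.

An expanded clonotype has ≥ 2 cells; a shared clonotype is an expanded
clonotype observed in ≥ 2 distinct cell clusters. The sharing matrix's
off-diagonal (i, j) counts expanded clonotypes with cells in both clusters i
and j; the diagonal counts all unique clonotypes observed in the cluster —
the two conventions are intentionally different and both encoded. For the
cohort test, clonotypes are pooled across patients within a cohort; per
cluster, two 2×2 tables (shared vs unique; MC vs each control cohort) are
tested with a two-sided Fisher exact test, BH-adjusted across the testable
clusters of each comparison, and a cluster is flagged only when both
adjusted p-values are below 0.05. Clusters without expanded clonotypes in a
cohort are not testable and are excluded from the BH family. A per-patient
stratified variant (rank-sum on per-patient shared fractions) is available
behind a flag as a sensitivity analysis for pooling effects; a
Mantel–Haenszel stratification is not well-defined here because each patient
belongs to exactly one cohort. The cluster set over which sharing is
evaluated is an input, not inferred.

## Histology count regression

Probe-positive counts per image are modeled as a Poisson GLM
`count ~ cohort` with `log(DAPI total)` offset, MC as the reference level,
fitted by IRLS (relative deviance tolerance 1e-8, 50 iterations). For a
two-group model the fitted rate ratio equals the closed-form ratio of pooled
rates, which the tests verify exactly. Poisson p-values are Wald z;
quasi-Poisson inference estimates dispersion as Pearson χ²/df, scales the
standard errors by its square root, and recomputes p-values from a t
distribution on the residual df (the specific Wald statistics are this
package's choice; no canonical test is mandated by the procedure). A
dispersion numerically at zero (all counts at fitted means) is flagged
degenerate. Cohorts with all-zero counts put their coefficient at the
boundary and are flagged. Images are treated as independent units;
patient-level random effects are a noted extension, not implemented.

Two significance modes reflect the two assay workflows: **ihc** BH-adjusts
Poisson p-values across stains within each contrast and requires adjusted
p < 0.05 against *both* control cohorts; **rnascope** applies a raw p < 0.05
cutoff against both cohorts under each regression separately and reports
probes where Poisson and quasi-Poisson disagree. IHC counts (summed
high-power-field counts) default to no offset, with a flag to enable one,
since constant-exposure field sums need none. The speckle rule — a cell is
"high" for a speckle-pattern probe iff it shows at least 5 speckles — is a
pure threshold and is kept; image segmentation is out of scope, the input
boundary being the per-image count table.

## Synthetic data

The generator emulates the *structure* the pipeline consumes, not colonic
biology. Counts follow a gamma-Poisson (negative-binomial) model: gene-level
baseline means drawn log-normal (μ = −2, σ = 1.2 on the log scale),
dispersion shape θ = 10 (variance ≈ 2–3× the mean for well-expressed genes,
matching droplet UMI data). Each simulated cell type has a marker block —
its own markers plus a shared per-compartment program (real compartments
differ in broad programs, not only in curated markers) — whose genes sit at
a fixed baseline of 3 counts-in-expectation off-type and are multiplied by
the lift (default 5) in-type, i.e. defining markers at a few percent of the
transcriptome. A lift of 1 makes all cell types exchangeable, giving a
chance-level negative control. Mitochondrial content is planted per cell by
drawing a target fraction f (uniform on 0.01–0.10) and adding
Poisson(f/(1−f) × nuclear total) counts spread over the 13 `MT-` genes.
Cohort composition defaults encode the study conditions: 16/13/15
expression patients (MC / chronic diarrhea / unaffected), ~2000 cells per
patient, and an MC composition shift (cytotoxic and cycling CD8 Trm up,
resting CD8 Trm and plasma cells down, IgG:IgA plasma ratio up).

TCR repertoires plant 40 clonotypes per patient (8/6/5 patients per cohort)
with Geometric(0.5) sizes; expanded clonotypes spread over two clusters with
probability 0.30 in MC versus 0.05 in controls. CDR3s are unique by
construction (C…F over the 20-letter amino-acid alphabet), each clonotype
carrying one TRA and one TRB; configurable fractions of non-productive and
low-confidence contigs exercise filtering, and cells split over two
libraries with per-library clonotype numbering exercise merging. Histology
tables plant per-probe Poisson rates (8/8/9 slides per cohort, DAPI totals
log-normal around 500) with a two-fold MC rate by default and optional
gamma over-dispersion.

Each generator uses its own RNG stream derived from the master seed by a
fixed offset, so adding one generator call never perturbs another's output;
identical (config, seed) is byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: transcriptome-wide co-expression and pathway
structure, doublets, ambient RNA, batch effects between platforms (the
platform column is metadata only), UMI saturation, cell-size variation
beyond library-size randomness, biological coupling between a patient's
expression, TCR and histology draws, and within-patient image correlation.

## Problem sizes

Tests and the acceptance script run scaled-down replicates chosen to keep a
full run fast on one CPU while leaving the statistical behavior measurable:
compartment recovery uses 6 patients × 800 cells × 300 genes per seed
(10 seeds in the test suite, 5 in the script); the null DE calibration uses
the full 13 + 15 control patients at 300 cells and 2000 genes; sharing
detection/null use the study-sized 8/6/5-patient repertoires (50/200
replicates in the suite, 50/100 in the script); interval coverage uses
100-image two-cohort designs (1000/500 replicates); dispersion calibration
uses 500-image designs. The generator's own defaults remain the full study
conditions.

## Known limitations

* The Leiden resolution scale is not interchangeable with other backends'
  scales; stability selection, not a fixed resolution, is the intended
  interface.
* The rank-sum pseudobulk engine has limited power at very small patient
  counts (its minimum two-sided p with 4 + 4 patients is ~0.029), which is
  intrinsic to rank tests, not a defect; the export path exists for GLM
  engines.
* Fisher + BH on small repertoires is conservative (observed null dual-flag
  rates well below the nominal 5%).
* Per-cell compartment scoring (cluster-free) is intentionally unsupported;
  the compartment unit is the cluster.
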