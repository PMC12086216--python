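# scolitis

A tested, reusable Python implementation of the computational pipeline used in
cohort-comparison single-cell studies of **microscopic colitis (MC)** — a
chronic large-intestine inflammation diagnosed histologically despite
normal-appearing mucosa — against chronic-diarrhea and unaffected control
cohorts. It is aimed at computational biologists who want the bespoke analysis
stages of such a study as well-specified library functions rather than ad hoc
scripts, and at methodologists who want to probe those stages on synthetic
data with known ground truth.

The pipeline covers:

* **Cell QC** — remove cells with fewer than 200 detected genes or more than
  20% mitochondrial UMI content (`MT-` prefix); exact-boundary cells are kept.
* **Compartment assignment** — score each expression cluster per compartment
  as the mean over curated marker genes *g* of the mean log-normalized
  expression, `score(c, k) = mean_{g in M_k} mean_{i in c} x_ig`, and assign
  by argmax (immune / epithelial / stromal).
* **Cluster stability** — at each candidate resolution, recluster 20
  subsamples of 90% of the cells and compare each to the full-data labeling
  with the Hubert–Arabie adjusted Rand index (ARI); select the largest
  resolution before the median ARI starts decreasing.
* **Compositional analysis** — per-patient cell-type proportions under
  configurable denominators, cohort enrichment stacks, the IgG/IgA
  plasma-cell ratio, and a patients × cell-types count export for external
  compositional models (scCODA layout).
* **Pseudobulk differential expression** — sum raw counts per
  (patient, cell type), drop groups under 5 cells, and compare cohorts per
  gene with a Wilcoxon rank-sum test on patient-level log2-CPM, BH-adjusted.
* **TCR clonotype analysis** — merge productive, high-confidence contigs by
  CDR3 set; Shannon diversity `H = −Σ pᵢ ln pᵢ`; expanded (≥ 2 cells) and
  shared (expanded, ≥ 2 clusters) clonotypes; cluster × cluster sharing
  matrices; per-cluster 2×2 Fisher tests of shared-vs-unique counts against
  both control cohorts with BH adjustment and a both-comparisons
  significance rule.
* **Histology regression** — probe-positive cell counts modeled as
  `count ~ cohort` Poisson GLM with `log(DAPI total)` offset (MC reference),
  quasi-Poisson dispersion correction (Pearson χ²/df), the ≥ 5-speckle
  high-expression rule, and dual-comparison significance for IHC/RNAscope.
* **Synthetic data** (`scolitis.synthetic`) — negative-binomial count
  matrices with planted marker blocks, composition shifts, mitochondrial
  content, clonal expansion/sharing, and Poisson rate ratios, all
  reproducible from a single seed.

## Worked example

```python
import numpy as np
from scolitis import synthetic as syn, qc, tcr
from scolitis.compartments import assign_compartments

cfg = syn.SimConfig(
    n_patients_per_cohort={"MC": 2, "chronic_diarrhea": 2, "unaffected": 2},
    n_cells_per_patient=800, n_genes=300, seed=1)
adata, truth = syn.generate_cell_dataset(cfg)

filtered, report = qc.filter_cells(
    adata, qc.QCThresholds(min_genes=100, max_mito_fraction=0.20))
print(report.cells_in, "->", report.cells_out)          # 4800 -> 3150

parts, scores = assign_compartments(filtered, resolution=2.0, seed=0)
print({k: v.n_obs for k, v in parts.items()})
# {'epithelial': 386, 'stromal': 107, 'immune': 2657}

pred = scores.cell_clusters.map(scores.assignment)
acc = (pred == truth.cells.loc[list(filtered.obs_names), "compartment"]).mean()
print(round(float(acc), 4))                              # 0.9949

reps, _ = syn.generate_repertoire(cfg)
by_cohort = {}
for r in reps:
    by_cohort.setdefault(r.cohort, []).append(r)
res = tcr.sharing_test(by_cohort, list(cfg.clonal_spec.clusters))
print(res[["cluster", "shared_MC", "unique_MC", "dual_significant"]])
```

The QC report says 1650 of 4800 simulated cells fell below the (scaled)
gene-detection floor. Compartment assignment recovers 99.5% of the planted
immune/epithelial/stromal labels. The sharing test, here run on repertoires
planted with 30% cross-cluster sharing in MC versus 5% in controls, flags
four of five CD8 clusters as dual-significant (adjusted p < 0.05 against
*both* control cohorts), e.g. CD8_Trm_GZMhi with 21 shared / 22 unique
expanded clonotypes in MC against 1 / 21 in unaffected controls
(p_adj 0.0013 and 0.0004).

Every stage is also exposed on the command line (`scolitis simulate`,
`scolitis qc`, `scolitis compartments`, `scolitis stability`,
`scolitis composition`, `scolitis pseudobulk`, `scolitis tcr`,
`scolitis histology`); all I/O is plain text (Matrix-Market + TSV/CSV/JSON).

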