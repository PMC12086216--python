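"""Pseudobulk aggregation and cohort differential expression.

Raw counts are summed per (patient, cell type) group; groups with fewer than
5 cells are dropped.  The built-in comparison engine is a Wilcoxon rank-sum
test on patient-level pseudobulk log2-CPM values — robust, assumption-light,
and testable by enumeration.  The pseudobulk layout is also exportable for
external GLM engines (limma-voom / edgeR style pipelines), which this module
deliberately does not re-implement.  Benjamini–Hochberg adjustment is applied
over genes, per comparison and per cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkMatrix:
    """Gene x group summed raw counts with group metadata.

    ``counts``: DataFrame indexed by gene, one integer column per group id
    ``"<patient>|<cell_type>"``; ``groups``: DataFrame indexed by group id
    with patient, cell_type, cohort and n_cells columns.
    """

    counts: pd.DataFrame
    groups: pd.DataFrame
    min_cells: int


def aggregate(
    dataset: ad.AnnData,
    min_cells: int = 5,
    patient_column: str = "patient",
    cell_type_column: str = "cell_type",
    cohort_column: str = "cohort",
) -> PseudobulkMatrix:
    """Sum raw counts per (patient, cell type); drop groups under ``min_cells``.

    Sums are exact integer arithmetic; column sums equal the summed totals of
    the member cells (conservation).
    """
    obs = dataset.obs
    for col in (patient_column, cell_type_column):
        if col not in obs.columns:
            raise ValueError(f"cells lack required column {col!r}")
    X = dataset.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    X = X.astype(np.int64)

    key = obs[patient_column].astype(str) + "|" + obs[cell_type_column].astype(str)
    group_ids, inverse = np.unique(key.to_numpy(), return_inverse=True)
    sizes = np.bincount(inverse, minlength=len(group_ids))
    indicator = sp.csr_matrix(
        (np.ones(len(inverse), dtype=np.int64), (inverse, np.arange(len(inverse)))),
        shape=(len(group_ids), X.shape[0]),
    )
    sums = np.asarray((indicator @ X).todense())  # groups x genes

    keep = sizes >= min_cells
    if not keep.any():
        raise ValueError(f"no groups with at least {min_cells} cells")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d pseudobulk groups with < %d cells", dropped, min_cells)

    kept_ids = group_ids[keep]
    counts = pd.DataFrame(
        sums[keep].T, index=pd.Index(dataset.var_names, name="gene"), columns=kept_ids
    )
    meta_rows = []
    cohort_of_patient = (
        obs.groupby(patient_column, observed=True)[cohort_column].first()
        if cohort_column in obs.columns
        else None
    )
    for gid, size in zip(kept_ids, sizes[keep]):
        patient, cell_type = gid.split("|", 1)
        meta_rows.append(
            {
                "patient": patient,
                "cell_type": cell_type,
                "cohort": None if cohort_of_patient is None else cohort_of_patient.get(patient),
                "n_cells": int(size),
            }
        )
    groups = pd.DataFrame(meta_rows, index=pd.Index(kept_ids, name="group"))
    return PseudobulkMatrix(counts=counts, groups=groups, min_cells=min_cells)


def cpm_log(pb: PseudobulkMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Counts-per-million per group column, then log2(x + pseudocount)."""
    totals = pb.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-sum pseudobulk groups: {list(zero.index)}")
    cpm = pb.counts / totals * 1e6
    return np.log2(cpm + pseudocount)


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Wilcoxon–Mann–Whitney rank-sum test (two-sided).

    Uses the exact null when min(n_a, n_b) <= 8 and there are no ties, and
    the tie-corrected normal approximation otherwise.  Returns (U statistic
    of the first sample, two-sided p).  If every value is identical across
    both groups the data are degenerate and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohort_de(
    pb: PseudobulkMatrix,
    cell_type: str,
    cohort_pair: tuple[str, str] = ("MC", "unaffected"),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene rank-sum comparison of two cohorts within one cell type.

    Each patient contributes one pseudobulk log2-CPM value per gene; the
    log2 fold change is mean(side 1) - mean(side 2) of those values.  BH
    adjustment is applied over genes within this comparison.  Requires at
    least 2 patient groups per side.
    """
    side_a, side_b = cohort_pair
    logcpm = cpm_log(pb, pseudocount=pseudocount)
    mask_type = pb.groups["cell_type"] == cell_type
    cols_a = pb.groups.index[mask_type & (pb.groups["cohort"] == side_a)]
    cols_b = pb.groups.index[mask_type & (pb.groups["cohort"] == side_b)]
    for cohort, cols in ((side_a, cols_a), (side_b, cols_b)):
        if len(cols) < 2:
            raise ValueError(
                f"cell type {cell_type!r} has {len(cols)} patient groups in cohort "
                f"{cohort!r}; need at least 2"
            )
    va = logcpm[cols_a].to_numpy()
    vb = logcpm[cols_b].to_numpy()
    stats = np.empty(va.shape[0])
    pvals = np.empty(va.shape[0])
    for i in range(va.shape[0]):
        stats[i], pvals[i] = rank_sum_test(va[i], vb[i])
    result = pd.DataFrame(
        {
            "gene": logcpm.index,
            "cell_type": cell_type,
            "comparison": f"{side_a} vs {side_b}",
            "log2fc": va.mean(axis=1) - vb.mean(axis=1),
            "mean_log2cpm_a": va.mean(axis=1),
            "mean_log2cpm_b": vb.mean(axis=1),
            "stat": stats,
            "p": pvals,
        }
    )
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    return result


def marker_de(
    normalized: ad.AnnData,
    labeling,
    cluster,
    min_log2fc: float = 0.25,
    min_fraction: float = 0.10,
) -> pd.DataFrame:
    """One-cluster-vs-rest Wilcoxon marker test at the single-cell level.

    ``normalized`` holds log-normalized expression; ``labeling`` maps cells
    to clusters.  Genes are BH-adjusted over the whole panel; ``top``
    candidates can then be filtered on ``log2fc`` and the fraction of
    cluster cells expressing the gene (thresholds are reported alongside,
    not applied destructively).
    """
    labels = pd.Series(getattr(labeling, "labels", labeling)).reindex(normalized.obs_names)
    in_cluster = (labels == cluster).to_numpy()
    if in_cluster.sum() < 2 or (~in_cluster).sum() < 2:
        raise ValueError("need at least 2 cells inside and outside the cluster")
    X = normalized.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    inside, outside = X[in_cluster], X[~in_cluster]
    stats = np.empty(X.shape[1])
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        stats[j], pvals[j] = rank_sum_test(inside[:, j], outside[:, j])
    log2fc = (inside.mean(axis=0) - outside.mean(axis=0)) / np.log(2)
    frac_in = (inside > 0).mean(axis=0)
    out = pd.DataFrame(
        {
            "gene": normalized.var_names,
            "cluster": cluster,
            "log2fc": log2fc,
            "fraction_expressing": frac_in,
            "stat": stats,
            "p": pvals,
        }
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["candidate"] = (out["p_adj"] < 0.05) & (out["log2fc"] >= min_log2fc) & (
        out["fraction_expressing"] >= min_fraction
    )
    return out


#: Cytokine / chemokine panel derived from Gene Ontology "cytokine activity"
#: and "chemokine activity" terms (static snapshot, retrieved 2025-09; shipped
#: rather than fetched live).
CYTOKINE_GENES = (
    "IFNG", "IL10", "IL26", "IL17A", "IL21", "IL22", "IL2", "IL4", "IL6",
    "IL1A", "IL1B", "IL15", "IL18", "IL23A", "IL12A", "IL12B", "IL32",
    "TNF", "TNFSF4", "TNFSF10", "TNFSF13B", "TGFB1", "LTA", "LTB",
    "CXCL1", "CXCL2", "CXCL8", "CXCL9", "CXCL10", "CXCL11", "CXCL13",
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL20", "CCL25", "XCL1", "XCL2",
)
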