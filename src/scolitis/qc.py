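"""Post-droplet-calling cell filters.

Cells are removed when fewer than ``min_genes`` unique genes are detected or
when more than ``max_mito_fraction`` of their UMIs come from mitochondrial
genes (gene names starting with ``mito_prefix``).  The boundary convention is
strict on both sides: a cell with exactly ``min_genes`` detected genes, or
exactly ``max_mito_fraction`` mitochondrial content, is retained.

Droplet calling itself (EmptyDrops-style knee / FDR selection) is not part of
this module — it consumes already-called barcodes and records the upstream
parameters as provenance metadata only.  Mitochondrial "content" is computed
as a fraction of total UMI counts, the standard convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np

logger = logging.getLogger(__name__)

#: Upstream droplet-calling parameters, recorded as provenance only.
DROPLET_CALLING_PROVENANCE = {
    "algorithm": "EmptyDrops",
    "lower_umi_bound": 100,
    "fdr_threshold": 0.01,
    "keep_above_knee": True,
}


class ZeroTotalCountError(ValueError):
    """A cell with zero total counts has no defined mitochondrial fraction."""


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 200
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Tallies of the filtering pass.

    A cell failing both rules is counted in both per-rule tallies, so
    ``cells_out + cells_removed_low_genes + cells_removed_high_mito`` can
    exceed ``cells_in``; ``cells_out`` equals ``cells_in`` minus the number of
    cells failing either rule.
    """

    cells_in: int
    cells_removed_low_genes: int
    cells_removed_high_mito: int
    cells_removed_manual: int
    cells_out: int
    thresholds: QCThresholds
    provenance: dict = field(default_factory=lambda: dict(DROPLET_CALLING_PROVENANCE))

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_removed_low_genes": self.cells_removed_low_genes,
            "cells_removed_high_mito": self.cells_removed_high_mito,
            "cells_removed_manual": self.cells_removed_manual,
            "cells_out": self.cells_out,
            "min_genes": self.thresholds.min_genes,
            "max_mito_fraction": self.thresholds.max_mito_fraction,
            "provenance": dict(self.provenance),
        }


def mito_fraction(cell_counts, gene_names, mito_prefix: str = "MT-") -> float:
    """Fraction of a single cell's total counts on ``mito_prefix`` genes.

    Raises :class:`ZeroTotalCountError` when the cell has zero total counts
    (such a cell must be removed upstream; its fraction is undefined).
    """
    counts = np.asarray(cell_counts, dtype=float).ravel()
    names = np.asarray(gene_names, dtype=object)
    if counts.shape[0] != names.shape[0]:
        raise ValueError("cell_counts and gene_names lengths differ")
    total = counts.sum()
    if total <= 0:
        raise ZeroTotalCountError("cell has zero total counts; mito fraction undefined")
    is_mito = np.array([str(g).startswith(mito_prefix) for g in names])
    return float(counts[is_mito].sum() / total)


def _per_cell_stats(adata: ad.AnnData, mito_prefix: str):
    X = adata.X
    is_mito = np.array([str(g).startswith(mito_prefix) for g in adata.var_names])
    if hasattr(X, "tocsr"):
        X = X.tocsr()
        totals = np.asarray(X.sum(axis=1)).ravel()
        n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
        mito_totals = np.asarray(X[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros(X.shape[0])
    else:
        X = np.asarray(X)
        totals = X.sum(axis=1)
        n_detected = (X > 0).sum(axis=1)
        mito_totals = X[:, is_mito].sum(axis=1) if is_mito.any() else np.zeros(X.shape[0])
    return totals, n_detected, mito_totals


def filter_cells(
    adata: ad.AnnData,
    thresholds: QCThresholds = QCThresholds(),
    manual_exclude: set[str] | None = None,
) -> tuple[ad.AnnData, QCReport]:
    """Apply the gene-count and mitochondrial-content filters.

    ``manual_exclude`` is an optional explicit barcode blacklist covering the
    study-specific manual removals (an overloaded library; clusters defined
    solely by mitochondrial genes), which are curation decisions rather than
    a reproducible rule.

    Returns the filtered dataset (metadata rows subset consistently) and a
    :class:`QCReport`.  An empty result is not an error; a warning is emitted.
    """
    if adata.n_obs == 0:
        raise ValueError("empty input dataset")
    totals, n_detected, mito_totals = _per_cell_stats(adata, thresholds.mito_prefix)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)

    low_genes = n_detected < thresholds.min_genes
    high_mito = frac > thresholds.max_mito_fraction
    # zero-total cells have no defined fraction: always removed, tallied as low-gene
    zero_total = totals == 0
    low_genes = low_genes | zero_total

    manual = np.zeros(adata.n_obs, dtype=bool)
    if manual_exclude:
        manual = adata.obs_names.isin(list(manual_exclude))

    keep = ~(low_genes | high_mito | manual)
    report = QCReport(
        cells_in=int(adata.n_obs),
        cells_removed_low_genes=int(low_genes.sum()),
        cells_removed_high_mito=int(high_mito.sum()),
        cells_removed_manual=int(manual.sum()),
        cells_out=int(keep.sum()),
        thresholds=thresholds,
    )
    if report.cells_out == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    logger.info(
        "QC: %d cells in, %d removed (low genes %d, high mito %d, manual %d), %d out",
        report.cells_in,
        report.cells_in - report.cells_out,
        report.cells_removed_low_genes,
        report.cells_removed_high_mito,
        report.cells_removed_manual,
        report.cells_out,
    )
    return adata[keep].copy(), report
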