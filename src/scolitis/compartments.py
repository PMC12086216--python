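"""Immune / epithelial / stromal compartment assignment by marker scores.

Clusters are scored per compartment as the mean (over the compartment's
curated marker genes) of the mean log-normalized expression over the
cluster's cells, and each cluster is named for its maximum score.  The
curated lists are fixed colonic-mucosa compartment markers; CD16 is not a
current HGNC symbol and is matched to FCGR3A through a small alias table.

Normalization is counts-per-10,000 followed by log1p.  Ties between
compartment scores are broken by a fixed order (immune > epithelial >
stromal) with a logged warning; real data essentially never ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Fixed tie-break priority between compartments.
COMPARTMENT_ORDER = ("immune", "epithelial", "stromal")

#: Gene-symbol aliases applied before marker matching.
GENE_ALIASES = {"CD16": "FCGR3A"}

DEFAULT_MARKER_SETS: dict[str, tuple[str, ...]] = {
    "epithelial": ("EPCAM", "KRT8", "KRT18"),
    "stromal": ("COL1A1", "COL1A2", "COL6A1", "COL6A2", "VWF", "PLVAP", "CDH5", "S100B"),
    "immune": (
        "CD52", "CD2", "CD3D", "CD3G", "CD3E", "CD79A", "CD79B",
        "CD14", "CD16", "CD68", "CD83", "CSF1R", "FCER1G",
    ),
}


class MarkerSetError(ValueError):
    """Raised when a compartment has no marker gene present in the data."""


def validate_marker_sets(markers: dict[str, tuple[str, ...]]) -> None:
    seen: dict[str, str] = {}
    for compartment, genes in markers.items():
        if not genes:
            raise MarkerSetError(f"marker list for {compartment!r} is empty")
        for g in genes:
            resolved = GENE_ALIASES.get(g, g)
            if resolved in seen and seen[resolved] != compartment:
                raise MarkerSetError(
                    f"gene {g!r} appears in both {seen[resolved]!r} and {compartment!r}"
                )
            seen[resolved] = compartment


@dataclass
class CompartmentScores:
    """Cluster x compartment score matrix with the argmax assignment."""

    scores: pd.DataFrame  # index: cluster, columns: compartment
    assignment: pd.Series  # cluster -> compartment
    margin: pd.Series  # cluster -> top score minus runner-up
    cell_clusters: pd.Series = field(repr=False, default=None)  # barcode -> cluster


def normalize_log(adata: ad.AnnData, scale_total: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``scale_total`` total counts, then log1p.

    Zero counts map to zero; cells with zero total counts are an error (QC
    should have removed them) and are reported by barcode.
    """
    X = adata.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr().copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = list(np.asarray(adata.obs_names)[zero][:10])
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad}")
    X = X.astype(float)
    scale = scale_total / totals
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    out = adata.copy()
    out.X = X.tocsr()
    return out


def _resolve_markers(markers: dict[str, tuple[str, ...]], var_names) -> dict[str, list[str]]:
    present = set(var_names)
    resolved: dict[str, list[str]] = {}
    for compartment, genes in markers.items():
        hits = []
        for g in genes:
            name = g if g in present else GENE_ALIASES.get(g, g)
            if name in present:
                hits.append(name)
                if name != g:
                    logger.info("marker %s matched via alias %s", g, name)
            else:
                logger.warning("marker gene %s not found; skipped", g)
        if not hits:
            raise MarkerSetError(f"no marker genes for compartment {compartment!r} found in data")
        resolved[compartment] = hits
    return resolved


def score_clusters(
    normalized: ad.AnnData,
    labeling,
    markers: dict[str, tuple[str, ...]] | None = None,
) -> CompartmentScores:
    """Score every cluster against every compartment's marker set.

    ``labeling`` is a barcode -> cluster mapping (a pandas Series or a
    :class:`scolitis.stability.ClusterLabeling`); every cell must be labeled.
    score(cluster, compartment) = mean over present marker genes of the mean
    normalized expression over the cluster's cells.
    """
    markers = dict(markers or DEFAULT_MARKER_SETS)
    validate_marker_sets(markers)
    labels = getattr(labeling, "labels", labeling)
    labels = pd.Series(labels).reindex(normalized.obs_names)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()][:10])
        raise ValueError(f"cells without cluster labels: {missing}")

    resolved = _resolve_markers(markers, normalized.var_names)
    all_genes = sorted({g for gs in resolved.values() for g in gs})
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    sub = normalized[:, all_genes].X
    sub = sub.toarray() if sp.issparse(sub) else np.asarray(sub)

    clusters = pd.unique(labels)
    rows = []
    for cluster in clusters:
        mask = (labels == cluster).to_numpy()
        cluster_mean = sub[mask].mean(axis=0)
        rows.append(
            [cluster_mean[[gene_pos[g] for g in resolved[c]]].mean() for c in markers]
        )
    scores = pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"), columns=list(markers))

    order = [c for c in COMPARTMENT_ORDER if c in scores.columns] + [
        c for c in scores.columns if c not in COMPARTMENT_ORDER
    ]
    ordered = scores[order]
    assignment = ordered.idxmax(axis=1)  # idxmax takes the first maximum -> fixed priority
    top2 = np.sort(ordered.to_numpy(), axis=1)[:, -2:]
    margin = pd.Series(top2[:, 1] - top2[:, 0], index=scores.index, name="margin")
    ties = margin == 0
    if ties.any():
        logger.warning(
            "compartment score tie in clusters %s; broken by fixed order %s",
            list(scores.index[ties]),
            order,
        )
    return CompartmentScores(
        scores=scores,
        assignment=assignment.rename("compartment"),
        margin=margin,
        cell_clusters=labels,
    )


def split_dataset(adata: ad.AnnData, scores: CompartmentScores) -> dict[str, ad.AnnData]:
    """Partition the cells by their cluster's assigned compartment.

    Every compartment named in the scores is a key of the result, including
    compartments to which no cluster was assigned (empty dataset).
    """
    labels = scores.cell_clusters.reindex(adata.obs_names)
    if labels.isna().any():
        raise ValueError("scores do not cover all cells in the dataset")
    unknown = set(labels.unique()) - set(scores.assignment.index)
    if unknown:
        raise ValueError(f"clusters without compartment scores: {sorted(map(str, unknown))}")
    cell_compartment = labels.map(scores.assignment)
    out: dict[str, ad.AnnData] = {}
    for compartment in scores.scores.columns:
        mask = (cell_compartment == compartment).to_numpy()
        out[compartment] = adata[mask].copy()
    return out


def assign_compartments(
    adata: ad.AnnData,
    resolution: float = 2.0,
    seed: int = 0,
    markers: dict[str, tuple[str, ...]] | None = None,
    scale_total: float = 1e4,
) -> tuple[dict[str, ad.AnnData], CompartmentScores]:
    """End-to-end compartment separation: cluster, score, split.

    Clusters the dataset with the default graph-clustering backend at the
    given resolution (2.0 by default, the standard high-resolution setting
    for compartment separation), scores clusters against the curated marker
    sets, and partitions the cells.
    """
    from .stability import default_cluster

    normalized = normalize_log(adata, scale_total=scale_total)
    labeling = default_cluster(adata, resolution=resolution, seed=seed)
    scores = score_clusters(normalized, labeling, markers=markers)
    return split_dataset(adata, scores), scores
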