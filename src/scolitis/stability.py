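"""Cluster-stability evaluation and resolution selection.

The procedure follows the bootstrap-like scheme: cluster the full dataset at
each candidate resolution, then repeatedly (20 iterations by default)
subsample 90% of the cells without replacement, recluster with a fresh
derived seed, and compare the subsample labeling with the full-data labeling
restricted to the subsample using the adjusted Rand index (ARI).  The chosen
resolution is the largest one before the median ARI starts decreasing.

The default clustering backend mirrors the standard single-cell pipeline:
log-normalization, per-gene z-scaling (clipped at 10), PCA (50 components),
a k-nearest-neighbor shared-nearest-neighbor (SNN) graph with Jaccard
weights (k = 20, prune below 1/15), and Leiden modularity optimization at
the given resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class ClusterLabeling:
    """A cell -> cluster assignment with its provenance (resolution, seed)."""

    labels: pd.Series  # barcode -> cluster id
    resolution: float
    seed: int

    def __post_init__(self):
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate barcodes in labeling")


@dataclass
class StabilityCurve:
    """ARI values per (resolution, iteration) plus per-resolution medians."""

    values: pd.DataFrame  # columns: resolution, iteration, ari
    frac: float
    n_iter: int
    seed: int
    selection_tolerance: float | None = field(default=None)

    def medians(self) -> pd.Series:
        med = self.values.groupby("resolution")["ari"].median()
        return med.sort_index()


def _as_label_series(labeling) -> pd.Series:
    labels = getattr(labeling, "labels", labeling)
    return pd.Series(labels)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Accepts :class:`ClusterLabeling` objects or barcode-indexed Series; the
    comparison is over the intersection of the two barcode sets (so a
    subsample can be compared against a full-data labeling).  Returns 1.0 for
    identical partitions and is invariant to cluster relabeling.
    """
    plain = not (
        hasattr(labels_a, "labels") or hasattr(labels_b, "labels")
        or isinstance(labels_a, (pd.Series, dict)) or isinstance(labels_b, (pd.Series, dict))
    )
    if plain:  # positional labels: compare directly, no barcode alignment
        av = np.asarray(labels_a)
        bv = np.asarray(labels_b)
        if av.shape != bv.shape:
            raise ValueError("positional labelings must have equal length")
        n = av.shape[0]
        if n < 2:
            raise ValueError("fewer than 2 common barcodes between labelings")
    else:
        a = _as_label_series(labels_a)
        b = _as_label_series(labels_b)
        common = a.index.intersection(b.index)
        if len(common) < 2:
            raise ValueError("fewer than 2 common barcodes between labelings")
        av = a.loc[common].to_numpy()
        bv = b.loc[common].to_numpy()
        n = len(common)

    # pair-counting contingency table
    _, ai = np.unique(av, return_inverse=True)
    _, bi = np.unique(bv, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    sum_comb_cells = comb(table, 2).sum()
    sum_comb_rows = comb(table.sum(axis=1), 2).sum()
    sum_comb_cols = comb(table.sum(axis=0), 2).sum()
    total_pairs = comb(n, 2)
    expected = sum_comb_rows * sum_comb_cols / total_pairs
    max_index = 0.5 * (sum_comb_rows + sum_comb_cols)
    if max_index == expected:  # both partitions trivial (all-singleton or single-block)
        return 1.0
    return float((sum_comb_cells - expected) / (max_index - expected))


def _snn_graph(embedding: np.ndarray, n_neighbors: int, prune: float = 1 / 15) -> igraph.Graph:
    n = embedding.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    # neighbor sets include the cell itself, the Seurat convention
    neighbor_sets = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i, row in enumerate(idx):
        si = neighbor_sets[i]
        for j in row:
            j = int(j)
            if j <= i:
                continue
            sj = neighbor_sets[j]
            jac = len(si & sj) / len(si | sj)
            if jac >= prune:
                edges.append((i, j))
                weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def default_cluster(
    dataset,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 20,
) -> ClusterLabeling:
    """Graph-based community detection: PCA -> SNN graph -> Leiden modularity.

    ``dataset`` is an AnnData of raw counts (log-normalized internally) or a
    dense array of already-processed values.  Deterministic given the seed.
    """
    from .compartments import normalize_log

    if hasattr(dataset, "obs_names"):
        if dataset.n_obs < 2:
            raise ValueError("need at least 2 cells to cluster")
        normalized = normalize_log(dataset)
        X = normalized.X
        X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
        # per-gene z-scaling, clipped, so a few high-mean genes cannot dominate PCA
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = np.clip((X - X.mean(axis=0)) / sd, -10, 10)
        index = pd.Index(dataset.obs_names)
    else:
        X = np.asarray(dataset, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 cells to cluster")
        index = pd.RangeIndex(X.shape[0])

    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    emb = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)
    if n_neighbors >= X.shape[0]:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n_cells={X.shape[0]}; truncated", stacklevel=2
        )
    graph = _snn_graph(emb, n_neighbors)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed) % (2**31 - 1),
        n_iterations=2,
    )
    labels = pd.Series(partition.membership, index=index, name="cluster")
    return ClusterLabeling(labels=labels, resolution=resolution, seed=seed)


def _derived_seed(seed: int, res_idx: int, iteration: int) -> int:
    # fixed arithmetic derivation: reproducible, distinct per (resolution, iteration)
    return (int(seed) * 1_000_003 + res_idx * 10_007 + iteration) % (2**31 - 1)


def stability_profile(
    dataset,
    resolutions,
    frac: float = 0.9,
    n_iter: int = 20,
    cluster_fn=None,
    seed: int = 0,
) -> StabilityCurve:
    """Subsampled-ARI stability curve over a grid of resolutions.

    For each resolution the full dataset is clustered once; then ``n_iter``
    subsamples of ``floor(frac * n)`` cells (without replacement, fresh
    derived seed each) are reclustered and compared against the full-data
    labeling restricted to the subsample.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    resolutions = list(resolutions)
    if sorted(resolutions) != resolutions:
        raise ValueError("resolutions must be sorted ascending")
    cluster_fn = cluster_fn or default_cluster

    n = dataset.n_obs if hasattr(dataset, "n_obs") else np.asarray(dataset).shape[0]
    barcodes = (
        pd.Index(dataset.obs_names) if hasattr(dataset, "obs_names") else pd.RangeIndex(n)
    )
    m = int(np.floor(frac * n))

    rows = []
    for res_idx, resolution in enumerate(resolutions):
        try:
            full = cluster_fn(dataset, resolution, seed)
        except Exception as err:
            raise RuntimeError(
                f"cluster_fn failed at resolution={resolution} on the full data"
            ) from err
        for iteration in range(n_iter):
            sub_seed = _derived_seed(seed, res_idx, iteration + 1)
            rng = np.random.default_rng(sub_seed)
            pick = np.sort(rng.choice(n, size=m, replace=False))
            subset = dataset[pick] if hasattr(dataset, "obs_names") else np.asarray(dataset)[pick]
            try:
                sub_labeling = cluster_fn(subset, resolution, sub_seed)
            except Exception as err:  # annotate failures with their context
                raise RuntimeError(
                    f"cluster_fn failed at resolution={resolution}, iteration={iteration}"
                ) from err
            sub_labels = _as_label_series(sub_labeling)
            if not hasattr(dataset, "obs_names"):
                sub_labels.index = barcodes[pick]
            ari = adjusted_rand_index(full, sub_labels)
            rows.append({"resolution": resolution, "iteration": iteration, "ari": ari})
    values = pd.DataFrame(rows)
    return StabilityCurve(values=values, frac=frac, n_iter=n_iter, seed=seed)


def select_resolution(curve: StabilityCurve, tolerance: float = 0.01) -> float:
    """Largest resolution before the median ARI starts decreasing.

    Scanning medians in ascending resolution, returns the resolution
    immediately preceding the first drop exceeding ``tolerance`` (raw medians
    jitter, so an exact-decrease rule would be seed-sensitive); with no such
    drop, the largest tested resolution.  Pure function of the curve.
    """
    med = curve.medians()
    if med.empty:
        raise ValueError("empty stability curve")
    resolutions = list(med.index)
    values = med.to_numpy()
    for i in range(len(values) - 1):
        if values[i + 1] < values[i] - tolerance:
            logger.info(
                "median ARI drops %.4f -> %.4f after resolution %s (tolerance %.3g)",
                values[i], values[i + 1], resolutions[i], tolerance,
            )
            curve.selection_tolerance = tolerance
            return resolutions[i]
    curve.selection_tolerance = tolerance
    return resolutions[-1]
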