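"""TCR clonotype analysis: merging, diversity, expansion and sharing.

Contigs are filtered to productive AND high-confidence calls; the set of
retained CDR3 amino-acid sequences of a barcode defines its clonotype, and
identical sets across a patient's libraries collapse to one clonotype with
pooled cells.  An expanded clonotype has >= 2 member cells; a shared
clonotype is an expanded clonotype present in >= 2 distinct cell clusters.
Shannon diversity is computed with the natural log over per-clonotype cell
counts of clonotype-bearing cells.

Cluster-level sharing differences between cohorts are assessed per cluster
with two 2x2 Fisher exact tests (MC vs chronic diarrhea, MC vs unaffected)
on shared-vs-unique counts of expanded clonotypes, clonotypes pooled across
patients within a cohort; BH adjustment runs across the testable clusters of
each comparison, and a cluster is flagged only when both adjusted p-values
fall below 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .pseudobulk import bh_adjust

logger = logging.getLogger(__name__)

_TRUE_STRINGS = {"true", "t", "yes", "1", "1.0"}


def _truthy(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in _TRUE_STRINGS


@dataclass
class Repertoire:
    """One patient's merged clonotype table.

    ``clonotypes`` maps clonotype ID -> (frozenset of CDR3 sequences, set of
    member cell barcodes); equal CDR3 sets are, by construction, the same
    clonotype.  ``cell_clusters`` maps barcodes to their expression-analysis
    cluster where known.
    """

    patient: str
    cohort: str | None
    clonotypes: dict[str, tuple[frozenset, set]]
    cell_clusters: dict[str, str] = field(default_factory=dict)

    def n_cells(self) -> int:
        return sum(len(bcs) for _, bcs in self.clonotypes.values())


def merge_clonotypes(
    contigs: pd.DataFrame,
    patient: str,
    cohort: str | None = None,
    cell_clusters: dict[str, str] | pd.Series | None = None,
) -> Repertoire:
    """Merge one patient's contigs (possibly several libraries) into clonotypes.

    Contigs are filtered to productive AND high-confidence; per barcode the
    set of retained CDR3 sequences is the merge key, so the same CDR3 set
    observed in different libraries collapses into a single clonotype with a
    new patient-level ID.  Duplicate (barcode, chain, cdr3) rows are
    deduplicated with a warning.
    """
    df = contigs.copy()
    for col in ("barcode", "chain", "cdr3", "productive", "high_confidence"):
        if col not in df.columns:
            raise ValueError(f"contig table lacks required column {col!r}")
    dup = df.duplicated(subset=["barcode", "chain", "cdr3"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (barcode, chain, cdr3) contig rows deduplicated",
            stacklevel=2,
        )
        df = df[~dup]
    ok = df["productive"].map(_truthy) & df["high_confidence"].map(_truthy)
    df = df[ok & df["cdr3"].notna() & (df["cdr3"].astype(str) != "")]

    by_barcode: dict[str, set] = {}
    for barcode, cdr3 in zip(df["barcode"], df["cdr3"]):
        by_barcode.setdefault(barcode, set()).add(str(cdr3))

    by_key: dict[frozenset, set] = {}
    for barcode, cdr3s in by_barcode.items():
        by_key.setdefault(frozenset(cdr3s), set()).add(barcode)

    # deterministic IDs: order by sorted CDR3 tuple
    clonotypes: dict[str, tuple[frozenset, set]] = {}
    for i, key in enumerate(sorted(by_key, key=lambda k: tuple(sorted(k)))):
        clonotypes[f"{patient}_CT{i:03d}"] = (key, by_key[key])

    clusters: dict[str, str] = {}
    if cell_clusters is not None:
        series = pd.Series(cell_clusters)
        clusters = {str(k): v for k, v in series.items()}
    return Repertoire(
        patient=patient, cohort=cohort, clonotypes=clonotypes, cell_clusters=clusters
    )


def clonotype_frequencies(rep: Repertoire) -> pd.DataFrame:
    """Per-clonotype cell counts and proportions of clonotype-bearing cells."""
    if not rep.clonotypes:
        raise ValueError(f"repertoire for patient {rep.patient!r} is empty")
    rows = [
        {"clonotype_id": cid, "n_cells": len(bcs)} for cid, (_, bcs) in rep.clonotypes.items()
    ]
    out = pd.DataFrame(rows).sort_values("n_cells", ascending=False, kind="stable")
    out["proportion"] = out["n_cells"] / out["n_cells"].sum()
    out["patient"] = rep.patient
    out["cohort"] = rep.cohort
    return out.reset_index(drop=True)


def shannon_diversity(freqs) -> float:
    """Shannon diversity H = -sum(p_i ln p_i) over clonotype proportions.

    Accepts a frequency table from :func:`clonotype_frequencies`, raw cell
    counts, or proportions summing to 1.
    """
    if isinstance(freqs, pd.DataFrame):
        p = freqs["proportion"].to_numpy(dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.size and not np.isclose(p.sum(), 1.0):
            p = p / p.sum()
    if p.size == 0:
        raise ValueError("empty frequency input")
    if np.any(p <= 0):
        raise ValueError("proportions must be positive")
    return float(-(p * np.log(p)).sum())


def classify_expanded(rep: Repertoire) -> set[str]:
    """Clonotype IDs with at least 2 member cells."""
    return {cid for cid, (_, bcs) in rep.clonotypes.items() if len(bcs) >= 2}


def _clonotype_cluster_sets(reps: list[Repertoire]):
    """Per clonotype (patient-scoped): the set of clusters its cells occupy.

    Cells without a cluster label are excluded (count logged).
    """
    records = []
    unlabeled = 0
    for rep in reps:
        for cid, (_, bcs) in rep.clonotypes.items():
            clusters = set()
            for bc in bcs:
                cluster = rep.cell_clusters.get(bc)
                if cluster is None:
                    unlabeled += 1
                else:
                    clusters.add(cluster)
            records.append((rep.patient, cid, len(bcs), clusters))
    if unlabeled:
        logger.info("%d clonotype cells without cluster labels excluded", unlabeled)
    return records


def sharing_matrix(reps: list[Repertoire], clusters: list[str]) -> pd.DataFrame:
    """Cluster x cluster clonotype-sharing matrix (one cohort's repertoires pooled).

    Off-diagonal (i, j): expanded clonotypes with >= 1 cell in cluster i and
    >= 1 cell in cluster j.  Diagonal (i, i): total unique clonotypes (of any
    size) observed in cluster i.
    """
    clusters = list(clusters)
    mat = pd.DataFrame(0, index=clusters, columns=clusters, dtype=int)
    for _, _, n_cells, cluster_set in _clonotype_cluster_sets(reps):
        present = [c for c in clusters if c in cluster_set]
        for c in present:
            mat.loc[c, c] += 1
        if n_cells >= 2:
            for i, ci in enumerate(present):
                for cj in present[i + 1:]:
                    mat.loc[ci, cj] += 1
                    mat.loc[cj, ci] += 1
    return mat


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers.

    The two-sided p sums the hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's.  A zero margin forces p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer entries")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


def _shared_unique_counts(reps: list[Repertoire], cluster: str) -> tuple[int, int]:
    """Shared vs unique expanded clonotypes observed in one cluster, pooled."""
    shared = unique = 0
    for _, _, n_cells, cluster_set in _clonotype_cluster_sets(reps):
        if n_cells < 2 or cluster not in cluster_set:
            continue
        if len(cluster_set) >= 2:
            shared += 1
        else:
            unique += 1
    return shared, unique


def sharing_test(
    reps_by_cohort: dict[str, list[Repertoire]],
    clusters: list[str],
    reference: str = "MC",
    comparisons: tuple[str, ...] = ("chronic_diarrhea", "unaffected"),
    stratified: bool = False,
) -> pd.DataFrame:
    """Dual-cohort Fisher test of cluster-level clonotype sharing.

    For each cluster, two 2x2 contingency tables (shared vs unique expanded
    clonotypes; reference cohort vs each comparison cohort) are tested with
    a two-sided Fisher exact test.  P-values are BH-adjusted across the
    testable clusters within each comparison, and ``dual_significant`` is
    True only when both adjusted p-values are below 0.05.  Clusters with no
    expanded clonotypes in a cohort are flagged not-testable and excluded
    from the BH family.

    ``stratified=True`` replaces the pooled per-comparison Fisher test with a
    rank-sum test on per-patient shared fractions (sensitivity analysis for
    patient-level pooling effects; patients with no expanded clonotypes in
    the cluster drop out of that test).
    """
    missing = [c for c in (reference, *comparisons) if c not in reps_by_cohort]
    if missing:
        raise ValueError(f"cohorts missing from input: {missing}")

    rows = []
    for cluster in clusters:
        ref_shared, ref_unique = _shared_unique_counts(reps_by_cohort[reference], cluster)
        row = {"cluster": cluster, f"shared_{reference}": ref_shared,
               f"unique_{reference}": ref_unique}
        for cohort in comparisons:
            shared, unique = _shared_unique_counts(reps_by_cohort[cohort], cluster)
            row[f"shared_{cohort}"] = shared
            row[f"unique_{cohort}"] = unique
            testable = (ref_shared + ref_unique > 0) and (shared + unique > 0)
            row[f"testable_{cohort}"] = testable
            if not testable:
                row[f"p_{cohort}"] = np.nan
                continue
            if stratified:
                row[f"p_{cohort}"] = _per_patient_pvalue(
                    reps_by_cohort[reference], reps_by_cohort[cohort], cluster
                )
            else:
                row[f"p_{cohort}"] = fisher_exact_2x2(
                    [[ref_shared, ref_unique], [shared, unique]]
                )
        rows.append(row)
    out = pd.DataFrame(rows)

    for cohort in comparisons:
        adj = np.full(len(out), np.nan)
        mask = out[f"testable_{cohort}"].to_numpy()
        if mask.any():
            adj[mask] = bh_adjust(out.loc[mask, f"p_{cohort}"].to_numpy())
        out[f"p_adj_{cohort}"] = adj
    flags = np.ones(len(out), dtype=bool)
    for cohort in comparisons:
        flags &= out[f"testable_{cohort}"].to_numpy() & (
            out[f"p_adj_{cohort}"].to_numpy() < 0.05
        )
    out["dual_significant"] = flags
    return out


def _per_patient_pvalue(ref_reps, cmp_reps, cluster: str) -> float:
    """Rank-sum p on per-patient shared fractions (stratified sensitivity)."""
    from .pseudobulk import rank_sum_test

    fractions = []
    for reps in (ref_reps, cmp_reps):
        side = []
        for rep in reps:
            shared, unique = _shared_unique_counts([rep], cluster)
            if shared + unique > 0:
                side.append(shared / (shared + unique))
        fractions.append(side)
    if not fractions[0] or not fractions[1]:
        return np.nan
    return rank_sum_test(fractions[0], fractions[1])[1]
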