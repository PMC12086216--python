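"""Clonotype merging, diversity, expansion, sharing matrices and tests."""

import math

import numpy as np
import pandas as pd
import pytest

from scolitis import synthetic as syn
from scolitis import tcr


def _contig(barcode, chain, cdr3, productive="true", high_confidence="true"):
    return {
        "barcode": barcode,
        "is_cell": "true",
        "high_confidence": high_confidence,
        "chain": chain,
        "v_gene": f"{chain}V1",
        "j_gene": f"{chain}J1",
        "cdr3": cdr3,
        "cdr3_nt": "ACG",
        "productive": productive,
        "raw_clonotype_id": "clonotype1",
    }


def _rep(clonotypes, clusters=None):
    return tcr.Repertoire(
        patient="p1",
        cohort="MC",
        clonotypes=clonotypes,
        cell_clusters=clusters or {},
    )


# ------------------------------------------------------------- merge_clonotypes

def test_merge_pools_same_cdr3_set_across_libraries():
    """3 + 2 cells with one CDR3 set in two libraries give one 5-cell clonotype."""
    rows = []
    for i in range(3):
        rows += [_contig(f"lib1_bc{i}", "TRA", "CAAF"), _contig(f"lib1_bc{i}", "TRB", "CBBF")]
    for i in range(2):
        rows += [_contig(f"lib2_bc{i}", "TRA", "CAAF"), _contig(f"lib2_bc{i}", "TRB", "CBBF")]
    rep = tcr.merge_clonotypes(pd.DataFrame(rows), "p1")
    assert len(rep.clonotypes) == 1
    (cdr3s, barcodes), = rep.clonotypes.values()
    assert cdr3s == frozenset({"CAAF", "CBBF"})
    assert len(barcodes) == 5


def test_merge_filters_nonproductive_and_low_confidence():
    rows = [
        _contig("bc1", "TRA", "CAAF"),
        _contig("bc1", "TRB", "CJUNKF", productive="false"),
        _contig("bc1", "TRB", "CLOWF", high_confidence="false"),
    ]
    rep = tcr.merge_clonotypes(pd.DataFrame(rows), "p1")
    (cdr3s, _), = rep.clonotypes.values()
    assert cdr3s == frozenset({"CAAF"})


def test_merge_disjoint_sets_two_clonotypes():
    rows = [
        _contig("bc1", "TRA", "CAAF"),
        _contig("bc2", "TRA", "CXXF"),
    ]
    rep = tcr.merge_clonotypes(pd.DataFrame(rows), "p1")
    assert len(rep.clonotypes) == 2


def test_merge_deduplicates_with_warning():
    rows = [_contig("bc1", "TRA", "CAAF"), _contig("bc1", "TRA", "CAAF")]
    with pytest.warns(UserWarning, match="duplicate"):
        rep = tcr.merge_clonotypes(pd.DataFrame(rows), "p1")
    assert len(rep.clonotypes) == 1


def test_merge_idempotent_on_planted_tables(small_repertoires):
    """Merging the generator's contig tables reproduces the planted repertoires."""
    reps, truth = small_repertoires
    for rep in reps[:4]:
        merged = tcr.merge_clonotypes(
            truth.contig_tables[rep.patient], rep.patient, cohort=rep.cohort
        )
        planted = {cdr3s: frozenset(bcs) for cdr3s, bcs in rep.clonotypes.values()}
        recovered = {cdr3s: frozenset(bcs) for cdr3s, bcs in merged.clonotypes.values()}
        assert planted == recovered


# -------------------------------------------------------- frequencies, diversity

def test_frequencies_proportions():
    rep = _rep({
        "c1": (frozenset({"A"}), {"b1", "b2"}),
        "c2": (frozenset({"B"}), {"b3"}),
        "c3": (frozenset({"C"}), {"b4"}),
    })
    freqs = tcr.clonotype_frequencies(rep)
    assert list(freqs["proportion"]) == [0.5, 0.25, 0.25]
    assert freqs["proportion"].sum() == pytest.approx(1.0)


def test_frequencies_empty_error():
    with pytest.raises(ValueError, match="empty"):
        tcr.clonotype_frequencies(_rep({}))


def test_shannon_closed_forms():
    assert tcr.shannon_diversity(np.array([7])) == pytest.approx(0.0)
    for k in (2, 5, 11):
        assert tcr.shannon_diversity(np.ones(k)) == pytest.approx(math.log(k))
    assert tcr.shannon_diversity(np.array([2, 1, 1])) == pytest.approx(1.0397, abs=1e-4)


def test_shannon_relabeling_invariant_and_split_increases():
    counts = np.array([5, 3, 2])
    assert tcr.shannon_diversity(counts) == pytest.approx(
        tcr.shannon_diversity(counts[::-1])
    )
    # moving one cell from the largest clonotype to a new singleton adds diversity
    split = np.array([4, 3, 2, 1])
    assert tcr.shannon_diversity(split) > tcr.shannon_diversity(counts)


def test_shannon_empty_error():
    with pytest.raises(ValueError):
        tcr.shannon_diversity(np.array([]))


# ------------------------------------------------------------- classify_expanded

def test_expanded_boundary():
    rep = _rep({
        "single": (frozenset({"A"}), {"b1"}),
        "pair": (frozenset({"B"}), {"b2", "b3"}),
    })
    assert tcr.classify_expanded(rep) == {"pair"}
    assert tcr.classify_expanded(_rep({})) == set()


# --------------------------------------------------------------- sharing_matrix

def _sharing_reps():
    return [
        _rep(
            {
                "span": (frozenset({"A"}), {"b1", "b2"}),       # expanded, A+B
                "solo": (frozenset({"B"}), {"b3", "b4"}),       # expanded, only A
                "one": (frozenset({"C"}), {"b5"}),              # singleton in B
            },
            clusters={"b1": "A", "b2": "B", "b3": "A", "b4": "A", "b5": "B"},
        )
    ]


def test_sharing_matrix_entries():
    mat = tcr.sharing_matrix(_sharing_reps(), ["A", "B"])
    assert mat.loc["A", "B"] == 1 and mat.loc["B", "A"] == 1
    assert mat.loc["A", "A"] == 2  # span + solo observed in A
    assert mat.loc["B", "B"] == 2  # span + one observed in B


def test_sharing_matrix_symmetric_with_dominant_diagonal():
    reps, _ = syn.generate_repertoire(syn.SimConfig(seed=11))
    clusters = list(syn.ClonalSpec().clusters)
    mat = tcr.sharing_matrix(reps, clusters).to_numpy()
    assert (mat == mat.T).all()
    off = mat.copy()
    np.fill_diagonal(off, 0)
    assert (np.diag(mat) >= off.max(axis=1)).all()


def test_singleton_only_matrix_diagonal():
    rep = _rep(
        {f"c{i}": (frozenset({chr(65 + i)}), {f"b{i}"}) for i in range(7)},
        clusters={f"b{i}": "A" for i in range(7)},
    )
    mat = tcr.sharing_matrix([rep], ["A", "B"])
    assert mat.loc["A", "A"] == 7
    assert mat.loc["A", "B"] == 0


# -------------------------------------------------------------- fisher_exact_2x2

def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    from fractions import Fraction

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(x):
        return Fraction(
            math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)
        )

    observed = prob(a)
    cutoff = observed * Fraction(10**7 + 1, 10**7)  # relative tolerance 1e-7
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= cutoff:
            total += prob(x)
    return float(total)


def test_fisher_hand_example():
    assert tcr.fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(0.4857, abs=1e-4)
    assert tcr.fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(
        fisher_oracle([[3, 1], [1, 3]]), rel=1e-7
    )


def test_fisher_zero_margin():
    assert tcr.fisher_exact_2x2([[2, 2], [0, 0]]) == 1.0
    assert tcr.fisher_exact_2x2([[0, 0], [2, 2]]) == 1.0


def test_fisher_symmetry_under_exchanges():
    p = tcr.fisher_exact_2x2([[0, 5], [5, 0]])
    for t in ([[5, 0], [0, 5]], [[5, 0], [0, 5]]):
        assert tcr.fisher_exact_2x2(t) == pytest.approx(p)


def test_fisher_matches_oracle_small_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        t = rng.integers(0, 7, (2, 2))
        assert tcr.fisher_exact_2x2(t) == pytest.approx(
            fisher_oracle(t.tolist()), rel=1e-6, abs=1e-12
        )


def test_fisher_invalid_table():
    with pytest.raises(ValueError):
        tcr.fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


# ----------------------------------------------------------------- sharing_test

def _cohort_reps(share_mc=0.3, share_ctrl=0.05, seed=0):
    spec = syn.ClonalSpec(
        sharing_prob={
            "MC": share_mc,
            "chronic_diarrhea": share_ctrl,
            "unaffected": share_ctrl,
        }
    )
    reps, _ = syn.generate_repertoire(syn.SimConfig(seed=seed, clonal_spec=spec))
    by_cohort = {}
    for rep in reps:
        by_cohort.setdefault(rep.cohort, []).append(rep)
    return by_cohort, list(spec.clusters)


def test_sharing_test_detects_planted_excess():
    by_cohort, clusters = _cohort_reps(seed=21)
    res = tcr.sharing_test(by_cohort, clusters)
    assert res["dual_significant"].any()


def test_sharing_test_counts_are_consistent():
    by_cohort, clusters = _cohort_reps(seed=22)
    res = tcr.sharing_test(by_cohort, clusters)
    for _, row in res.iterrows():
        assert row["shared_MC"] >= 0 and row["unique_MC"] >= 0
    # shared + unique equals expanded clonotypes observed in the cluster
    total_expanded_in_clusters = sum(
        1
        for rep in by_cohort["MC"]
        for cid, (_, bcs) in rep.clonotypes.items()
        if len(bcs) >= 2
        and {rep.cell_clusters[b] for b in bcs} & set(clusters)
    )
    per_cluster = res["shared_MC"] + res["unique_MC"]
    assert per_cluster.sum() >= total_expanded_in_clusters  # shared counted per cluster


def test_single_comparison_significance_never_dual_flagged():
    """A cluster significant against only one control cohort stays unflagged."""

    def rep_with(n_shared, n_unique, patient, cohort):
        clonotypes, clusters = {}, {}
        for i in range(n_shared):
            b1, b2 = f"{patient}s{i}a", f"{patient}s{i}b"
            clonotypes[f"{patient}_s{i}"] = (frozenset({f"{patient}S{i}"}), {b1, b2})
            clusters[b1], clusters[b2] = "X", "Y"
        for i in range(n_unique):
            b1, b2 = f"{patient}u{i}a", f"{patient}u{i}b"
            clonotypes[f"{patient}_u{i}"] = (frozenset({f"{patient}U{i}"}), {b1, b2})
            clusters[b1] = clusters[b2] = "X"
        return tcr.Repertoire(patient, cohort, clonotypes, clusters)

    by_cohort = {
        "MC": [rep_with(18, 2, "mc", "MC")],
        "chronic_diarrhea": [rep_with(2, 18, "cd", "chronic_diarrhea")],
        "unaffected": [rep_with(18, 2, "ua", "unaffected")],  # same as MC
    }
    res = tcr.sharing_test(by_cohort, ["X", "Y"])
    row = res[res["cluster"] == "X"].iloc[0]
    assert row["p_adj_chronic_diarrhea"] < 0.05
    assert row["p_adj_unaffected"] > 0.05
    assert not row["dual_significant"]


def test_cluster_absent_from_cohort_not_testable():
    by_cohort, clusters = _cohort_reps(seed=23)
    res = tcr.sharing_test(by_cohort, clusters + ["GHOST"])
    ghost = res[res["cluster"] == "GHOST"].iloc[0]
    assert not ghost["testable_chronic_diarrhea"]
    assert np.isnan(ghost["p_chronic_diarrhea"])
    assert not ghost["dual_significant"]


def test_sharing_test_missing_cohort_error():
    by_cohort, clusters = _cohort_reps(seed=24)
    del by_cohort["unaffected"]
    with pytest.raises(ValueError, match="unaffected"):
        tcr.sharing_test(by_cohort, clusters)


def test_sharing_test_stratified_variant_runs():
    by_cohort, clusters = _cohort_reps(seed=25)
    res = tcr.sharing_test(by_cohort, clusters, stratified=True)
    assert {"dual_significant", "p_chronic_diarrhea"} <= set(res.columns)
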