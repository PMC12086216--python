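"""Pseudobulk aggregation, normalization, rank-sum engine, BH adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scolitis import pseudobulk as pb
from conftest import make_adata


def _labeled_adata(counts, genes, patients, cell_types, cohorts=None):
    obs = {"patient": patients, "cell_type": cell_types}
    if cohorts is not None:
        obs["cohort"] = cohorts
    return make_adata(counts, genes, obs=obs)


# -------------------------------------------------------------------- aggregate

def test_aggregate_sums_and_min_cells():
    """A 4-cell group is dropped; a 5-cell group's column is the exact sum."""
    counts = [[1, 2], [3, 4]] + [[1, 0]] * 4 + [[2, 1]] * 5
    patients = ["pA"] * 2 + ["pB"] * 4 + ["pC"] * 5
    types = ["T"] * 11
    adata = _labeled_adata(counts, ["g1", "g2"], patients, types)
    agg = pb.aggregate(adata, min_cells=5)
    assert set(agg.counts.columns) == {"pC|T"}
    assert list(agg.counts["pC|T"]) == [10, 5]

    agg2 = pb.aggregate(adata, min_cells=2)
    assert list(agg2.counts["pA|T"]) == [4, 6]
    assert "pB|T" in agg2.counts.columns


def test_aggregate_conservation_exact():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, (40, 6))
    patients = [f"p{i % 4}" for i in range(40)]
    types = ["T" if i % 2 else "B" for i in range(40)]
    adata = _labeled_adata(counts, [f"g{j}" for j in range(6)], patients, types)
    agg = pb.aggregate(adata, min_cells=1)
    assert agg.counts.to_numpy().sum() == counts.sum()
    assert (agg.groups["n_cells"].sum()) == 40


def test_aggregate_no_groups_error():
    adata = _labeled_adata([[1, 1]], ["g1", "g2"], ["p1"], ["T"])
    with pytest.raises(ValueError, match="at least 5"):
        pb.aggregate(adata, min_cells=5)


# ---------------------------------------------------------------------- cpm_log

def test_cpm_log_example():
    counts = pd.DataFrame({"grp": [1, 0]}, index=["g1", "g2"])
    groups = pd.DataFrame(
        {"patient": ["p"], "cell_type": ["T"], "cohort": ["MC"], "n_cells": [5]},
        index=["grp"],
    )
    mat = pb.PseudobulkMatrix(counts, groups, 5)
    out = pb.cpm_log(mat)
    assert out.loc["g1", "grp"] == pytest.approx(np.log2(1e6 + 1))
    assert out.loc["g2", "grp"] == 0.0


def test_cpm_log_scale_invariance():
    c1 = pd.DataFrame({"a": [3, 7, 10]}, index=list("xyz"))
    c2 = c1 * 2
    groups = pd.DataFrame(
        {"patient": ["p"], "cell_type": ["T"], "cohort": ["MC"], "n_cells": [5]},
        index=["a"],
    )
    out1 = pb.cpm_log(pb.PseudobulkMatrix(c1, groups, 5))
    out2 = pb.cpm_log(pb.PseudobulkMatrix(c2, groups, 5))
    pd.testing.assert_frame_equal(out1, out2)


def test_cpm_log_zero_column_error():
    counts = pd.DataFrame({"bad": [0, 0]}, index=["g1", "g2"])
    groups = pd.DataFrame(
        {"patient": ["p"], "cell_type": ["T"], "cohort": ["MC"], "n_cells": [5]},
        index=["bad"],
    )
    with pytest.raises(ValueError, match="bad"):
        pb.cpm_log(pb.PseudobulkMatrix(counts, groups, 5))


# ----------------------------------------------------------------- rank_sum_test

def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided p over all C(n+m, n) rank assignments."""
    pooled = sorted(a) + sorted(b)
    n = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in a)
    total = 0
    at_least = 0
    mean = n * (len(pooled) + 1) / 2
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        total += 1
        if abs(sum(combo) - mean) >= abs(obs - mean) - 1e-12:
            at_least += 1
    return at_least / total


def test_rank_sum_exact_extreme():
    """{1,2,3} vs {4,5,6} is the most extreme ranking: exact p = 0.1."""
    stat, p = pb.rank_sum_test([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)
    assert p == pytest.approx(exact_rank_sum_p([1, 2, 3], [4, 5, 6]))


def test_rank_sum_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = list(rng.normal(size=4))
        b = list(rng.normal(size=5))
        _, p = pb.rank_sum_test(a, b)
        assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-10)


def test_rank_sum_identical_groups():
    _, p = pb.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0, abs=0.05)
    _, p_degenerate = pb.rank_sum_test([2.0, 2.0], [2.0, 2.0])
    assert p_degenerate == 1.0


def test_rank_sum_swap_symmetry():
    a, b = [1.2, 3.4, 2.2], [0.1, 5.5, 2.9, 4.0]
    _, p1 = pb.rank_sum_test(a, b)
    _, p2 = pb.rank_sum_test(b, a)
    assert p1 == pytest.approx(p2)


def test_rank_sum_empty_error():
    with pytest.raises(ValueError, match="nonempty"):
        pb.rank_sum_test([], [1.0])


# -------------------------------------------------------------------- bh_adjust

def step_up_oracle(p):
    """Reference BH: adj_i = min_{j >= i}(p_(j) * m / j), input order preserved."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def test_bh_hand_example():
    assert np.allclose(pb.bh_adjust([0.005, 0.02, 0.03]), [0.015, 0.03, 0.03])


def test_bh_single_and_equal():
    assert pb.bh_adjust([0.3]) == pytest.approx([0.3])
    assert np.allclose(pb.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        assert np.allclose(pb.bh_adjust(p), step_up_oracle(p))


def test_bh_invalid_p_rejected():
    with pytest.raises(ValueError):
        pb.bh_adjust([0.5, 1.2])


def test_bh_adjusted_at_least_raw():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=25)
    adj = pb.bh_adjust(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


# -------------------------------------------------------------------- cohort_de

def _cohort_adata(seed=0, planted_fold=4.0, n_patients=8, n_cells=40, n_genes=30):
    rng = np.random.default_rng(seed)
    gmeans = rng.lognormal(-0.5, 0.8, n_genes)
    blocks, patients, cohorts = [], [], []
    for cohort in ("MC", "unaffected"):
        mult = np.ones(n_genes)
        if cohort == "MC":
            mult[0] = planted_fold
        for p in range(n_patients):
            lam = rng.gamma(10.0, gmeans * mult / 10.0, size=(n_cells, n_genes))
            blocks.append(rng.poisson(lam))
            patients += [f"{cohort}{p}"] * n_cells
            cohorts += [cohort] * n_cells
    counts = np.vstack(blocks)
    return _labeled_adata(
        counts,
        [f"g{j}" for j in range(n_genes)],
        patients,
        ["T"] * len(patients),
        cohorts,
    )


def test_cohort_de_recovers_planted_gene():
    adata = _cohort_adata(seed=3)
    res = pb.cohort_de(pb.aggregate(adata), "T", ("MC", "unaffected"))
    top = res.sort_values("p").iloc[0]
    assert top["gene"] == "g0"
    assert top["p_adj"] < 0.05
    assert top["log2fc"] > 1.0


def test_cohort_de_all_zero_gene():
    adata = _cohort_adata(seed=4)
    zeroed = adata.copy()
    x = zeroed.X.toarray()
    x[:, 5] = 0
    zeroed.X = x
    res = pb.cohort_de(pb.aggregate(zeroed), "T", ("MC", "unaffected"))
    row = res[res["gene"] == "g5"].iloc[0]
    assert row["log2fc"] == 0.0
    assert row["p"] == 1.0


def test_cohort_de_requires_two_patients_per_side():
    adata = _cohort_adata(n_patients=1)
    with pytest.raises(ValueError, match="at least 2"):
        pb.cohort_de(pb.aggregate(adata), "T", ("MC", "unaffected"))


def test_cohort_de_patient_label_permutation_invariant():
    """Renaming patients within a cohort leaves every statistic unchanged."""
    adata = _cohort_adata(seed=5)
    res1 = pb.cohort_de(pb.aggregate(adata), "T", ("MC", "unaffected"))
    renamed = adata.copy()
    swap = {"MC0": "MC1", "MC1": "MC0"}
    renamed.obs["patient"] = renamed.obs["patient"].map(lambda p: swap.get(p, p))
    res2 = pb.cohort_de(pb.aggregate(renamed), "T", ("MC", "unaffected"))
    assert np.allclose(res1["p"], res2["p"])
    assert np.allclose(res1["log2fc"], res2["log2fc"])


# -------------------------------------------------------------------- marker_de

def test_marker_de_flags_cluster_marker():
    rng = np.random.default_rng(6)
    base = rng.poisson(2.0, (60, 10)).astype(float)
    base[:30, 0] += 8  # cluster 0 strongly expresses g0
    adata = make_adata(base, [f"g{j}" for j in range(10)])
    labels = pd.Series([0] * 30 + [1] * 30, index=adata.obs_names)
    res = pb.marker_de(adata, labels, 0)
    row = res[res["gene"] == "g0"].iloc[0]
    assert row["p_adj"] < 0.05
    assert row["candidate"]
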