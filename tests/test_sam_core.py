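import numpy as np
import pytest

from samgsr import (PermutationEngine, compute_sam_statistics, fudge_factor,
                    permutation_pvalues, qvalues, samgs_statistic)

from conftest import make_expr, random_expr


def all_cells(expr, genes=None):
    genes = genes if genes is not None else expr.genes
    return [(g, t) for g in genes for t in expr.timepoints]


# ---------------------------------------------------------------------------
# d_ij statistic
# ---------------------------------------------------------------------------

def test_d_matches_hand_formula():
    # diseased {1, 3}, control {0, 2} at a single (gene, timepoint)
    vals = np.array([[[1.0], [3.0], [0.0], [2.0]]])
    expr = make_expr(vals, y=[1, 1, 0, 0])
    sam = compute_sam_statistics(expr, fudge_method="fixed", fudge_constant=1e-300)
    # pooled within-class SD: sqrt((1/2 + 1/2) * (2 + 2) / 2) = sqrt(2)
    expected = (2.0 - 1.0) / np.sqrt(2.0)
    assert sam.d[0, 0] == pytest.approx(expected, abs=1e-12)
    assert sam.mean_d[0, 0] == 2.0 and sam.mean_c[0, 0] == 1.0
    assert sam.s[0, 0] == pytest.approx(np.sqrt(2.0), abs=1e-12)


def test_d_zero_when_class_means_equal(rng):
    vals = rng.standard_normal((3, 6, 2))
    vals[0, :, 0] = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    expr = make_expr(vals, y=[1, 1, 1, 0, 0, 0])
    sam = compute_sam_statistics(expr)
    assert sam.d[0, 0] == pytest.approx(0.0, abs=1e-15)


def test_d_antisymmetric_under_label_swap(small_expr):
    sam = compute_sam_statistics(small_expr)
    flipped = compute_sam_statistics(small_expr, labels=1 - small_expr.y)
    np.testing.assert_allclose(flipped.d, -sam.d, atol=1e-12)


def test_d_identity_holds_exactly(small_expr):
    sam = compute_sam_statistics(small_expr)
    np.testing.assert_allclose(
        sam.d, (sam.mean_d - sam.mean_c) / (sam.s + sam.s0[None, :]), rtol=1e-15
    )
    assert np.all(sam.s >= 0) and np.all(sam.s0 > 0)


def test_d_class_too_small_errors(rng):
    expr = make_expr(rng.standard_normal((2, 5, 2)), y=[1, 1, 0, 0, 0])
    with pytest.raises(ValueError, match=">=2"):
        compute_sam_statistics(expr, labels=np.array([1, 0, 0, 0, 0]))


def test_all_samples_pooling_option(small_expr):
    within = compute_sam_statistics(small_expr, pooling="within")
    allp = compute_sam_statistics(small_expr, pooling="all")
    assert not np.allclose(within.d, allp.d)
    X = small_expr.values
    j, g = 0, 0
    n = small_expr.n_subjects
    nd = int(small_expr.y.sum())
    s_all = np.sqrt((1 / nd + 1 / (n - nd)) *
                    np.sum((X[g, :, j] - X[g, :, j].mean()) ** 2) / (n - 1))
    assert allp.s[g, j] == pytest.approx(s_all, abs=1e-12)


# ---------------------------------------------------------------------------
# fudge factor
# ---------------------------------------------------------------------------

def test_fudge_median():
    assert fudge_factor(np.array([1.0, 2.0, 3.0])) == 2.0


def test_fudge_fixed():
    assert fudge_factor(np.array([1.0]), method="fixed", constant=0.1) == 0.1


def test_fudge_all_zero_floors_with_warning():
    with pytest.warns(UserWarning, match="floored"):
        s0 = fudge_factor(np.zeros(5))
    assert s0 > 0


def test_fudge_rejects_bad_input():
    with pytest.raises(ValueError):
        fudge_factor(np.array([]))
    with pytest.raises(ValueError):
        fudge_factor(np.array([-1.0]))
    with pytest.raises(ValueError):
        fudge_factor(np.array([1.0]), method="fixed", constant=None)


# ---------------------------------------------------------------------------
# SAMGS statistic
# ---------------------------------------------------------------------------

def test_samgs_single_cell(small_expr):
    sam = compute_sam_statistics(small_expr)
    sam.d[0, 0] = 3.0
    assert samgs_statistic(sam, [("G0", "t1")]) == pytest.approx(9.0)


def test_samgs_sign_invariance(small_expr):
    sam = compute_sam_statistics(small_expr)
    sam.d[0, :3] = [1.0, -2.0, 2.0]
    cells = [("G0", t) for t in ("t1", "t2", "t3")]
    assert samgs_statistic(sam, cells) == pytest.approx(9.0)


def test_samgs_brute_force(rng):
    expr = random_expr(rng, G=3, N=8, T=2)
    sam = compute_sam_statistics(expr)
    cells = all_cells(expr)
    brute = 0.0
    for g, t in cells:
        brute += sam.d[expr.gene_index(g), expr.timepoint_index(t)] ** 2
    assert samgs_statistic(sam, cells) == pytest.approx(brute, abs=1e-10)


def test_samgs_empty_errors(small_expr):
    sam = compute_sam_statistics(small_expr)
    with pytest.raises(ValueError, match="empty"):
        samgs_statistic(sam, [])


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

def test_constant_data_gives_p_one(constant_expr):
    res = permutation_pvalues(constant_expr,
                              {"S": all_cells(constant_expr)}, B=50, seed=0)
    assert res[0].p_value == 1.0


def test_same_seed_same_pvalues(small_expr):
    sets = {"A": all_cells(small_expr, ["G0", "G1"]),
            "B": all_cells(small_expr, ["G2"])}
    r1 = permutation_pvalues(small_expr, sets, B=200, seed=7)
    r2 = permutation_pvalues(small_expr, sets, B=200, seed=7)
    assert [x.p_value for x in r1] == [x.p_value for x in r2]


def test_pvalues_invariant_to_class_relabeling(small_expr):
    sets = {"A": all_cells(small_expr, ["G0", "G1"])}
    r1 = permutation_pvalues(small_expr, sets, B=300, seed=3)
    flipped = make_expr(small_expr.values, y=1 - small_expr.y)
    r2 = permutation_pvalues(flipped, sets, B=300, seed=3)
    assert r1[0].statistic == pytest.approx(r2[0].statistic, abs=1e-12)
    assert r1[0].p_value == pytest.approx(r2[0].p_value, abs=2 / 301)


def test_pvalue_bounds(small_expr):
    res = permutation_pvalues(small_expr, {"S": all_cells(small_expr)},
                              B=99, seed=1)
    assert 1 / 100 <= res[0].p_value <= 1.0


def test_empty_feature_set_errors(small_expr):
    with pytest.raises(ValueError, match="empty"):
        permutation_pvalues(small_expr, {"S": []}, B=10, seed=0)


def test_b_below_one_errors(small_expr):
    with pytest.raises(ValueError, match="B"):
        PermutationEngine(small_expr, B=0, seed=0)


def test_exhaustive_matches_direct_recompute(small_expr):
    """Regression: each permutation recomputes s0j, not the observed one."""
    eng = PermutationEngine(small_expr, B=20, seed=5)
    for b in (0, 7, 19):
        labels = eng._assign[b].astype(int)
        direct = compute_sam_statistics(small_expr, labels=labels)
        np.testing.assert_allclose(eng._perm_d2[b], direct.d ** 2, atol=1e-10)


def test_exhaustive_enumeration_count(rng):
    expr = random_expr(rng, G=3, N=6, T=2)  # 3 vs 3 -> C(6,3) = 20 splits
    eng = PermutationEngine(expr, exhaustive=True)
    assert eng.n_perm == 20


def test_mc_matches_exhaustive_within_2se(rng):
    expr = random_expr(rng, G=4, N=6, T=2)
    cells = all_cells(expr, ["G0", "G1"])
    _, p_ex = PermutationEngine(expr, exhaustive=True).set_pvalue(cells)
    B = 2000
    _, p_mc = PermutationEngine(expr, B=B, seed=11).set_pvalue(cells)
    se = np.sqrt(p_ex * (1 - p_ex) / B)
    assert abs(p_mc - p_ex) <= 2 * se + 2 / (B + 1)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def test_qvalues_single_identity():
    assert qvalues([0.04])[0] == pytest.approx(0.04)


def test_qvalues_hand_worked_bh():
    np.testing.assert_allclose(qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_qvalues_all_one():
    np.testing.assert_allclose(qvalues([1.0, 1.0]), [1.0, 1.0])


def test_qvalues_empty():
    assert len(qvalues([])) == 0


def test_qvalues_monotone_in_p(rng):
    p = rng.random(30)
    q = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all((q > 0) & (q <= 1))


def test_qvalues_reject_out_of_range():
    with pytest.raises(ValueError):
        qvalues([1.5])


def test_write_set_results_tsv(tmp_path, small_expr):
    import pandas as pd
    from samgsr import write_set_results
    res = permutation_pvalues(small_expr, {"A": all_cells(small_expr, ["G0"])},
                              B=50, seed=0)
    write_set_results(res, tmp_path / "res.tsv")
    df = pd.read_csv(tmp_path / "res.tsv", sep="\t")
    assert list(df.columns) == ["set_name", "statistic", "p", "q"]
    assert df.loc[0, "set_name"] == "A"
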