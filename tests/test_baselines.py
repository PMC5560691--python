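"""Imputation strategies and sequential test pipelines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import censorq as cq
from censorq.baselines import impute_knn, impute_lod, impute_mnv1, sequential_test

from conftest import grid_dataset


def _nan_frame(values):
    vals = np.asarray(values, float)
    return pd.DataFrame(vals, index=[f"t{i}" for i in range(vals.shape[0])],
                        columns=[f"s{j}" for j in range(vals.shape[1])])


class TestMNV1:
    def test_max_plus_one(self):
        m = _nan_frame([[-1.2, 0.3, np.nan], [0.0, 0.1, 0.2]])
        out = impute_mnv1(m)
        assert out.values.loc["t0", "s2"] == pytest.approx(1.3)

    def test_multiple_gaps_tie(self):
        m = _nan_frame([[np.nan, 0.5, np.nan, -0.5], [0, 0, 0, 0]])
        out = impute_mnv1(m)
        assert out.values.loc["t0", "s0"] == out.values.loc["t0", "s2"] == pytest.approx(1.5)

    def test_identity_without_gaps(self):
        m = _nan_frame([[1.0, 2.0], [3.0, 4.0]])
        pd.testing.assert_frame_equal(impute_mnv1(m).values, m)

    def test_imputed_strictly_above_expressed(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, size=(6, 8))
        vals[rng.random((6, 8)) < 0.2] = np.nan
        vals[:, 0] = 0.0  # keep every target partly expressed
        m = _nan_frame(vals)
        out = impute_mnv1(m).values
        for tid in m.index:
            gaps = m.loc[tid].isna()
            if gaps.any():
                assert (out.loc[tid, gaps] > m.loc[tid, ~gaps].max()).all()

    def test_fully_absent_target_rejected(self):
        with pytest.raises(ValueError):
            impute_mnv1(_nan_frame([[np.nan, np.nan], [0.0, 1.0]]))


class TestKNN:
    def test_duplicate_row_k1(self):
        m = _nan_frame([
            [1.0, 2.0, np.nan],
            [1.0, 2.0, 5.0],   # exact duplicate on shared samples
            [9.0, -9.0, 0.0],
        ])
        out = impute_knn(m, k=1)
        assert out.values.loc["t0", "s2"] == pytest.approx(5.0)

    def test_hand_computed_neighbors(self):
        m = _nan_frame([
            [0.0, 0.0, np.nan],
            [0.1, 0.1, 1.0],
            [-0.1, -0.1, 2.0],
            [5.0, 5.0, 3.0],
            [-5.0, -5.0, 4.0],
        ])
        # neighbors of t0 by scaled Euclidean distance: t1 and t2 (0.17),
        # then t3/t4 (8.66); k=2 -> mean(1.0, 2.0)
        out = impute_knn(m, k=2)
        assert out.values.loc["t0", "s2"] == pytest.approx(1.5)

    def test_identity_without_gaps(self):
        m = _nan_frame(np.arange(12.0).reshape(3, 4))
        pd.testing.assert_frame_equal(impute_knn(m, k=2).values, m)

    def test_matches_sklearn_knnimputer(self):
        """Independent cross-check: scikit-learn's KNNImputer implements the
        same scaled pairwise-complete metric and neighbor averaging."""
        sklearn_impute = pytest.importorskip("sklearn.impute")
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, size=(12, 9))
        # at most one gap per sample, so the nearest neighbors are always
        # expressed at the gap (the two implementations agree only where no
        # donor fallback is needed — fallback semantics are a documented
        # design choice of this module)
        for j, i in enumerate([0, 3, 5, 7, 9]):
            vals[i, j] = np.nan
        m = _nan_frame(vals)
        ours = impute_knn(m, k=3).values.to_numpy()
        # rows (targets) are the imputation neighbors
        ref = sklearn_impute.KNNImputer(n_neighbors=3, weights="uniform").fit_transform(vals)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValueError):
            impute_knn(_nan_frame([[1.0, np.nan], [0.0, 1.0]]), k=2)


class TestLODImpute:
    def test_no_censoring_equals_plain_mod(self, small_complete):
        ds, _ = small_complete
        out = impute_lod(ds)
        normalized, _ = cq.mod_normalize(ds)
        pd.testing.assert_frame_equal(out.values, normalized)

    def test_censored_cell_participates_at_lod(self):
        vals = np.array([[20.0, 40.0], [30.0, 31.0], [25.0, 26.0]])
        cens = np.zeros((3, 2), bool)
        cens[0, 1] = True
        ds = grid_dataset(vals, ["g1", "g2"], lod=40.0, censored=cens)
        out = impute_lod(ds)
        filled = vals.copy()
        row_means = filled.mean(axis=1)
        a = filled - row_means[:, None]
        expected = a - a.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-12)


class TestReferenceGeneNormalization:
    def test_lod_impute_subtracts_reference_means(self):
        vals = np.array([
            [20.0, 22.0],   # reference gene
            [24.0, 26.0],   # reference gene
            [30.0, 40.0],   # target of interest, (t2, s1) censored
        ])
        cens = np.zeros((3, 2), bool)
        cens[2, 1] = True
        ds = grid_dataset(vals, ["g1", "g2"], lod=40.0, censored=cens)
        ds.targets.loc[["t0", "t1"], "is_reference"] = 1
        out = impute_lod(ds, normalization="refgenes")
        # per-sample reference means: (22, 24); censored well imputed at 40
        expected = np.array([[-2.0, -2.0], [2.0, 2.0], [8.0, 16.0]])
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-12)

    def test_refgenes_requires_flags(self):
        vals = np.array([[20.0, 22.0], [24.0, 26.0]])
        ds = grid_dataset(vals, ["g1", "g2"], lod=40.0)
        with pytest.raises(ValueError):
            impute_lod(ds, normalization="refgenes")


class TestSequential:
    def test_identical_groups_null(self):
        m = _nan_frame([[1.0, 1.0, 1.0, 1.0]])
        from censorq.baselines import ImputedMatrix
        res = sequential_test(ImputedMatrix(m, "LOD"),
                              pd.Series(["g1", "g1", "g2", "g2"], index=m.columns))
        assert res["delta_hat"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.05, 10)
        b = rng.normal(2, 0.05, 10)
        m = _nan_frame([np.r_[a, b]])
        from censorq.baselines import ImputedMatrix
        res = sequential_test(ImputedMatrix(m, "LOD"),
                              pd.Series(["g1"] * 10 + ["g2"] * 10, index=m.columns))
        assert res["p_value"].iloc[0] < 1e-6
        assert res["delta_hat"].iloc[0] == pytest.approx(a.mean() - b.mean())

    def test_t_statistic_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        m = _nan_frame([np.r_[a, b]])
        from censorq.baselines import ImputedMatrix
        res = sequential_test(ImputedMatrix(m, "LOD"),
                              pd.Series(["g1"] * 4 + ["g2"] * 4, index=m.columns))
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 4))
        assert res["wald_stat"].iloc[0] == pytest.approx(t, abs=1e-12)

    def test_wilcoxon_with_ties_matches_textbook_formula(self):
        """Tie-corrected asymptotic rank-sum on MNV+1-style tied data,
        against the classical normal approximation computed by hand: ranks
        (1, 2, 6.5, 6.5 | 3, 4, 6.5, 6.5), U = 6, mean 8, tie-corrected
        variance (n1 n2 / 12)((n+1) - sum(t^3 - t)/(n(n-1)))."""
        a = [1.0, 2.0, 5.0, 5.0]
        b = [3.0, 4.0, 5.0, 5.0]
        n1 = n2 = 4
        n = n1 + n2
        U = 16.0 - n1 * (n1 + 1) / 2  # rank sum of group a = 1+2+6.5+6.5
        var = (n1 * n2 / 12) * ((n + 1) - (4 ** 3 - 4) / (n * (n - 1)))
        z = (U - n1 * n2 / 2 + 0.5) / np.sqrt(var)  # continuity correction
        p_expected = 2 * stats.norm.sf(abs(z))
        m = _nan_frame([a + b])
        from censorq.baselines import ImputedMatrix
        res = sequential_test(ImputedMatrix(m, "MNV+1"),
                              pd.Series(["g1"] * 4 + ["g2"] * 4, index=m.columns),
                              test="wilcoxon")
        assert res["p_value"].iloc[0] == pytest.approx(p_expected, abs=1e-10)

    def test_zero_variance_both_groups_warns(self):
        m = _nan_frame([[1.0, 1.0, 2.0, 2.0]])
        from censorq.baselines import ImputedMatrix
        with pytest.warns(RuntimeWarning):
            res = sequential_test(ImputedMatrix(m, "LOD"),
                                  pd.Series(["g1", "g1", "g2", "g2"], index=m.columns))
        assert res["p_value"].iloc[0] == 1.0


def test_zero_censoring_pipelines_identical(small_complete):
    """Imputation is a no-op on complete data: all three pipelines return the
    same table."""
    ds, _ = small_complete
    tables = {name: cq.sequential_pipeline(ds, impute=name, k=3) for name in
              ("lod", "mnv1", "knn")}
    for name in ("mnv1", "knn"):
        pd.testing.assert_frame_equal(tables["lod"], tables[name])
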