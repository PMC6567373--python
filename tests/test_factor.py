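"""EFA core: preprocessing, parallel analysis, extraction, rotation, scores.

The fitted loadings are cross-checked against statsmodels' principal-axis
factor extraction as an independent implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import physcap as pc
from physcap.factor import (FactorModel, assign_measures, check_variance,
                            factor_scores, parallel_analysis, preprocess,
                            varimax)
from physcap.synthetic import SyntheticFactorSpec, simulate_feature_matrix

from conftest import align_columns, congruence


def _planted_loadings(p_per_factor=5, k=2, value=0.8):
    L = np.zeros((p_per_factor * k, k))
    for j in range(k):
        L[j * p_per_factor:(j + 1) * p_per_factor, j] = value
    return pd.DataFrame(L, index=[f"m{i}" for i in range(p_per_factor * k)],
                        columns=[f"F{j + 1}" for j in range(k)])


class TestPreprocess:
    def test_standardization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, (200, 4)), columns=list("abcd"))
        out = preprocess(df, jerk_measures=[])
        assert np.abs(out.mean().to_numpy()).max() < 1e-10
        np.testing.assert_allclose(out.std(ddof=1).to_numpy(), 1.0)

    def test_lognormal_jerk_becomes_symmetric(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"NJS AP": np.exp(rng.normal(0, 1, 5000))})
        out = preprocess(df)
        assert abs(stats.skew(out["NJS AP"])) < 0.2

    def test_constant_column_error(self):
        df = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ValueError, match="constant"):
            preprocess(df, jerk_measures=[])

    def test_nonpositive_jerk_error(self):
        df = pd.DataFrame({"NJS AP": [1.0, -2.0, 3.0]})
        with pytest.raises(ValueError, match="NJS AP"):
            preprocess(df)


class TestParallelAnalysis:
    def test_pure_noise_retains_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((500, 20))
        assert parallel_analysis(X, seed=3) == 0

    def test_planted_two_factors(self):
        X = simulate_feature_matrix(
            SyntheticFactorSpec(_planted_loadings(value=0.8), n=500), seed=4)
        assert parallel_analysis(X.to_numpy(), seed=5) == 2

    def test_monotone_in_signal_strength(self):
        for seed in range(3):
            ks = []
            for value in (0.3, 0.9):
                X = simulate_feature_matrix(
                    SyntheticFactorSpec(_planted_loadings(value=value), n=300),
                    seed=100 + seed)
                ks.append(parallel_analysis(X.to_numpy(), seed=200 + seed))
            assert ks[1] >= ks[0]


class TestVarimax:
    def test_preserves_communalities(self):
        rng = np.random.default_rng(6)
        L = rng.normal(0, 0.5, (12, 3))
        rotated, R = varimax(L)
        np.testing.assert_allclose((rotated ** 2).sum(1), (L ** 2).sum(1),
                                   atol=1e-8)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)


class TestFit:
    def test_planted_structure_recovered(self):
        L_true = _planted_loadings(p_per_factor=6, k=3, value=0.75)
        X = simulate_feature_matrix(SyntheticFactorSpec(L_true, n=2000),
                                    seed=7)
        res = FactorModel(X, jerk_measures=[]).fit(n_factors=3)
        aligned = align_columns(res.loadings.to_numpy(), L_true.to_numpy())
        for j in range(3):
            assert congruence(aligned[:, j], L_true.to_numpy()[:, j]) > 0.95

    def test_cross_check_against_statsmodels(self):
        from statsmodels.multivariate.factor import Factor
        L_true = _planted_loadings(p_per_factor=5, k=2, value=0.7)
        X = simulate_feature_matrix(SyntheticFactorSpec(L_true, n=3000),
                                    seed=8)
        res = FactorModel(X, jerk_measures=[]).fit(n_factors=2)
        sm_res = Factor(X.to_numpy(), n_factor=2, method="pa").fit()
        sm_res.rotate("varimax")
        aligned = align_columns(np.asarray(sm_res.loadings),
                                res.loadings.to_numpy())
        for j in range(2):
            assert congruence(aligned[:, j], res.loadings.to_numpy()[:, j]) > 0.98

    def test_too_few_measures_error(self):
        X = pd.DataFrame(np.random.default_rng(9).normal(size=(50, 3)),
                         columns=list("abc"))
        with pytest.raises(ValueError, match="factors"):
            FactorModel(X, jerk_measures=[]).fit(n_factors=3)

    def test_fewer_subjects_than_measures_warns(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(10, 12)))
        X.columns = [f"m{i}" for i in range(12)]
        with pytest.warns(UserWarning, match="unstable"):
            FactorModel(X, jerk_measures=[])

    def test_cumulative_variance_accounting(self):
        X = simulate_feature_matrix(
            SyntheticFactorSpec(_planted_loadings(value=0.8), n=1000), seed=11)
        res = FactorModel(X, jerk_measures=[]).fit(n_factors=2)
        assert 0.0 < res.cumulative_variance <= 1.0
        assert res.cumulative_variance == pytest.approx(
            res.communalities.sum() / len(res.communalities))
        # rotation-invariant: communalities equal variance_explained total
        assert res.variance_explained.sum() == pytest.approx(
            res.cumulative_variance)


class TestAssignment:
    def test_published_qs_loadings(self, qs_loadings):
        assignment = assign_measures(qs_loadings, threshold=0.5)
        # loads > 0.5 on two factors but belongs to its maximum only
        assert assignment["SP Planar DISPL"] == "QS1"
        assert assignment["MV AP DISPL"] == "QS4"
        # highest absolute loading 0.230: unassigned
        assert assignment["SE ML"] is None
        assert assignment.notna().sum() == 19

    def test_all_zero_loadings(self):
        L = pd.DataFrame(np.zeros((4, 2)), columns=["F1", "F2"])
        assert assign_measures(L).notna().sum() == 0


class TestScores:
    def test_zero_mean_columns(self):
        X = simulate_feature_matrix(
            SyntheticFactorSpec(_planted_loadings(), n=400), seed=12)
        res = FactorModel(X, jerk_measures=[]).fit(n_factors=2)
        assert np.abs(res.scores.mean().to_numpy()).max() < 1e-10

    def test_orthogonal_structure_gives_uncorrelated_scores(self):
        X = simulate_feature_matrix(
            SyntheticFactorSpec(_planted_loadings(value=0.8), n=2000), seed=13)
        res = FactorModel(X, jerk_measures=[]).fit(n_factors=2)
        corr = res.scores.corr().to_numpy()
        assert abs(corr[0, 1]) < 0.1

    def test_noiseless_limit_recovers_latent_factors(self):
        L_true = _planted_loadings(p_per_factor=6, k=2, value=1.0)
        spec = SyntheticFactorSpec(L_true, n=2000, floor=1e-3)
        X, F = simulate_feature_matrix(spec, seed=14, return_factors=True)
        res = FactorModel(X, jerk_measures=[]).fit(n_factors=2)
        C = np.abs(np.corrcoef(res.scores.to_numpy().T, F.to_numpy().T))[:2, 2:]
        # after alignment each score column tracks one latent factor
        assert sorted(C.max(axis=1)) == pytest.approx([1.0, 1.0], abs=0.01)


class TestVarianceCheck:
    def test_pass_fail(self):
        assert check_variance(0.80)
        assert not check_variance(0.69)

    def test_published_cst_structure_meets_threshold(self):
        X = simulate_feature_matrix(SyntheticFactorSpec.for_test("cst"),
                                    seed=15)
        res = FactorModel(X, jerk_measures=[]).fit(n_factors=6)
        assert res.meets_variance(0.70)


def test_summary_and_loading_table():
    X = simulate_feature_matrix(
        SyntheticFactorSpec(_planted_loadings(value=0.8), n=500), seed=16)
    res = FactorModel(X, jerk_measures=[]).fit(n_factors=2)
    text = res.summary()
    assert "factors retained: 2" in text
    tab = res.loading_table()
    assert "CV%" in tab.index
    assert tab.loc["CV%"].iloc[-1] == pytest.approx(
        100 * res.cumulative_variance)
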