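"""Rank correlations, redundancy screen, KMO/alpha and the child factor model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import famnet as fn
from famnet.datatypes import MOTHER, FamnetError, SymptomTable
from famnet.preprocessing import _closed_form_loadings

from _oracles import hittner_oracle


def make_table(df, community=MOTHER):
    return SymptomTable(
        data=df,
        communities={c: community for c in df.columns},
        scales={c: "continuous" for c in df.columns},
    )


class TestSpearmanMatrix:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.arange(1, 30, dtype=float)
        df = pd.DataFrame({"a": x, "b": np.exp(x / 10)})
        corr = fn.spearman_matrix(make_table(df))
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_average_rank_oracle(self):
        # ranks of x=(1,2,2,3) are (1, 2.5, 2.5, 4); ranks of y=(1,3,2,4) are (1,3,2,4)
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        df = pd.DataFrame({"x": [1, 2, 2, 3], "y": [1, 3, 2, 4]})
        corr = fn.spearman_matrix(make_table(df))
        assert corr.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
        corr = fn.spearman_matrix(make_table(df))
        assert abs(corr.values[0, 1]) < 0.05

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [2.0, 2, 2, 2]})
        with pytest.raises(FamnetError, match="flat"):
            fn.spearman_matrix(make_table(df))

    def test_complete_case_n_effective(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, np.nan, 5], "b": [5.0, 3, 2, 1, 4]})
        corr = fn.spearman_matrix(make_table(df))
        assert corr.n_effective == 4


class TestDependentCorrTest:
    def test_equal_correlations_give_p_one(self):
        assert fn.dependent_corr_test(0.4, 0.4, 0.1, 200) == 1.0

    def test_matches_independent_hittner_implementation(self):
        got = fn.dependent_corr_test(0.6, 0.2, 0.3, 500)
        assert got == pytest.approx(hittner_oracle(0.6, 0.2, 0.3, 500), abs=1e-6)

    def test_p_monotone_decreasing_in_n(self):
        ps = [fn.dependent_corr_test(0.5, 0.3, 0.2, n) for n in (20, 50, 100, 500, 2000)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_perfect_correlation_rejected(self):
        with pytest.raises(FamnetError, match="Fisher"):
            fn.dependent_corr_test(1.0, 0.2, 0.1, 100)

    def test_steiger_variant_close_but_distinct(self):
        h = fn.dependent_corr_test(0.6, 0.2, 0.3, 500, method="hittner")
        s = fn.dependent_corr_test(0.6, 0.2, 0.3, 500, method="steiger")
        assert h == pytest.approx(s, abs=0.05)


class TestFindRedundantPairs:
    def build(self, rng, n=400):
        base = rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "m_a": base + 0.5 * rng.standard_normal(n),
                "m_b": base + 0.6 * rng.standard_normal(n),
                "m_c": rng.standard_normal(n),
                "m_d": 0.4 * base + rng.standard_normal(n),
            }
        )
        return df

    def test_duplicated_column_flagged_with_zero_proportion(self):
        rng = np.random.default_rng(1)
        df = self.build(rng)
        df["m_dup"] = df["m_a"] + 1e-9 * rng.standard_normal(len(df))
        res = fn.find_redundant_pairs(
            make_table(df), communities_to_screen=[MOTHER]
        )
        pairs = {(a, b): prop for a, b, _, prop in res.candidate_pairs}
        assert ("m_a", "m_dup") in pairs
        assert pairs[("m_a", "m_dup")] == 0.0

    def test_opposite_signed_profiles_not_flagged(self):
        rng = np.random.default_rng(2)
        n = 600
        base = rng.standard_normal(n)
        hub = rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "m_x": base + 0.45 * hub + 0.3 * rng.standard_normal(n),
                "m_y": base - 0.45 * hub + 0.3 * rng.standard_normal(n),
                "m_hub": hub,
            }
        )
        corr = fn.spearman_matrix(make_table(df))
        assert corr.values[0, 1] > 0.5  # the pair is highly correlated
        res = fn.find_redundant_pairs(make_table(df), communities_to_screen=[MOTHER])
        assert ("m_x", "m_y") not in res.flagged

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        df = self.build(rng)
        df["m_e"] = df["m_a"] + 0.3 * rng.standard_normal(len(df))
        df["m_f"] = df["m_b"] + 0.3 * rng.standard_normal(len(df))
        table = make_table(df)
        res = fn.find_redundant_pairs(table, communities_to_screen=[MOTHER])

        corr = fn.spearman_matrix(table)
        R, n = corr.values, corr.n_effective
        cols = list(df.columns)
        expected = set()
        for i in range(len(cols) - 1):
            for j in range(i + 1, len(cols)):
                if R[i, j] < 0.5:
                    continue
                ps = [
                    hittner_oracle(R[i, h], R[j, h], R[i, j], n)
                    for h in range(len(cols))
                    if h not in (i, j)
                ]
                if np.mean([p < 0.05 for p in ps]) < 0.25:
                    expected.add((cols[i], cols[j]))
        assert set(res.flagged) == expected

    def test_corr_min_above_max_returns_empty(self):
        rng = np.random.default_rng(4)
        res = fn.find_redundant_pairs(
            make_table(self.build(rng)), corr_min=0.999, communities_to_screen=[MOTHER]
        )
        assert res.candidate_pairs == []

    def test_threshold_bounds_validated(self):
        rng = np.random.default_rng(5)
        with pytest.raises(FamnetError, match="corr_min"):
            fn.find_redundant_pairs(
                make_table(self.build(rng)), corr_min=1.5, communities_to_screen=[MOTHER]
            )


class TestKMO:
    def test_equicorrelation_closed_form(self):
        # p=3, r=0.5: anti-image partial is r/(1+r)=1/3, so KMO = r^2/(r^2 + 1/9)
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        expected = 0.25 / (0.25 + (1.0 / 3.0) ** 2)
        assert fn.kmo(R) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((300, 4)) @ rng.uniform(0.3, 1, (4, 4))
        R = np.corrcoef(X, rowvar=False)
        perm = [2, 0, 3, 1]
        assert fn.kmo(R) == pytest.approx(fn.kmo(R[np.ix_(perm, perm)]), abs=1e-12)

    def test_diagonal_matrix_rejected(self):
        with pytest.raises(FamnetError, match="off-diagonal"):
            fn.kmo(np.eye(3))

    def test_factor_model_plateau_matches_population_value(self):
        # 3 waves with loadings 0.75: population correlation is 0.5625 off-diagonal
        lam = 0.75
        Rpop = np.full((3, 3), lam * lam)
        np.fill_diagonal(Rpop, 1.0)
        pop_kmo = fn.kmo(Rpop)
        rng = np.random.default_rng(7)
        f = rng.standard_normal(50_000)
        X = lam * f[:, None] + np.sqrt(1 - lam * lam) * rng.standard_normal((50_000, 3))
        sample_kmo = fn.kmo(np.corrcoef(X, rowvar=False))
        assert sample_kmo == pytest.approx(pop_kmo, abs=0.01)
        assert 0.65 < sample_kmo < 0.75


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        x = np.random.default_rng(8).standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x, "c": x})
        assert fn.cronbach_alpha(df) == pytest.approx(1.0)

    def test_toy_table_matches_direct_formula(self):
        X = np.array(
            [[1, 2, 2, 3], [2, 3, 3, 4], [3, 3, 2, 4], [4, 4, 3, 3], [2, 2, 1, 2]],
            dtype=float,
        )
        k = 4
        expected = k / (k - 1) * (
            1 - np.var(X, axis=0, ddof=1).sum() / np.var(X.sum(axis=1), ddof=1)
        )
        assert fn.cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 4)) + rng.standard_normal((40, 1))
        assert fn.cronbach_alpha(X) == pytest.approx(fn.cronbach_alpha(X[:, ::-1]))

    def test_zero_variance_rejected(self):
        with pytest.raises(FamnetError, match="variance"):
            fn.cronbach_alpha(np.ones((5, 3)))


def exact_cov_sample(S, n, seed):
    """Data whose sample covariance (ddof=1) equals S exactly."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, S.shape[0]))
    X = X - X.mean(axis=0)
    C = np.cov(X, rowvar=False, ddof=1)
    W = np.linalg.cholesky(np.linalg.inv(C))
    return X @ W @ np.linalg.cholesky(S).T


class TestFitOneFactor:
    def test_population_loadings_recovered_exactly(self):
        lam = np.array([0.8, 0.7, 0.6])
        S = np.outer(lam, lam) + np.diag(1 - lam**2)
        assert np.abs(_closed_form_loadings(S) - lam).max() < 1e-6

        df = pd.DataFrame(exact_cov_sample(S, 500, seed=10), columns=["w1", "w2", "w3"])
        res = fn.fit_one_factor(df)
        assert np.abs(res.loadings - lam).max() < 1e-6

    def test_matches_statsmodels_ml_oracle(self):
        from statsmodels.multivariate.factor import Factor

        rng = np.random.default_rng(11)
        f = rng.standard_normal(2000)
        X = 0.75 * f[:, None] + 0.6 * rng.standard_normal((2000, 3))
        df = pd.DataFrame(X, columns=["w1", "w2", "w3"])
        res = fn.fit_one_factor(df)
        sm = Factor(X, n_factor=1, method="ml").fit()
        # statsmodels works on the correlation scale; rescale to covariances
        sd = X.std(axis=0, ddof=1)
        sm_load = np.abs(sm.loadings[:, 0]) * sd
        assert np.abs(res.loadings - sm_load).max() < 0.01

    def test_scores_linear_in_indicators(self):
        rng = np.random.default_rng(12)
        f = rng.standard_normal(500)
        X = 0.75 * f[:, None] + 0.6 * rng.standard_normal((500, 3))
        df = pd.DataFrame(X, columns=["w1", "w2", "w3"])
        res = fn.fit_one_factor(df)
        # regressing the scores on the indicators reproduces them exactly
        design = np.column_stack([np.ones(len(df)), X])
        beta, *_ = np.linalg.lstsq(design, res.scores.to_numpy(), rcond=None)
        assert np.abs(design @ beta - res.scores.to_numpy()).max() < 1e-8
        assert res.scores.mean() == pytest.approx(0.0, abs=1e-10)

    def test_score_recovers_true_factor(self):
        rng = np.random.default_rng(13)
        f = rng.standard_normal(5000)
        X = 0.75 * f[:, None] + np.sqrt(1 - 0.75**2) * rng.standard_normal((5000, 3))
        res = fn.fit_one_factor(pd.DataFrame(X, columns=["w1", "w2", "w3"]))
        assert np.corrcoef(res.scores, f)[0, 1] >= 0.85

    def test_heywood_case_warns_and_clamps(self):
        S = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.5], [0.8, 0.5, 1.0]])
        df = pd.DataFrame(exact_cov_sample(S, 200, seed=14), columns=["w1", "w2", "w3"])
        with pytest.warns(UserWarning, match="Heywood"):
            res = fn.fit_one_factor(df)
        assert res.heywood
        assert (res.uniquenesses >= 1e-6 - 1e-15).all()

    def test_wrong_column_count_rejected(self):
        with pytest.raises(FamnetError, match="3 indicator"):
            fn.fit_one_factor(pd.DataFrame({"a": [1.0, 2, 3]}))
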