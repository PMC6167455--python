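"""Inferential layer: inverted-U regression, correlations, ICC."""

import numpy as np
import pandas as pd
import pytest

from assocfractal import (
    InvertedUModel,
    icc2k,
    pearson_test,
    quadratic_model_test,
    rt_smd_regression,
)
from assocfractal.errors import CollinearityError, InvalidInputError


# --------------------------------------------------------------------------
# independent OLS oracle via the normal equations


def ols_oracle(y, X):
    """Brute-force OLS: (X'X)^{-1} X'y with classical SEs, F and R^2."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = resid @ resid / df_resid
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    tss = np.sum((y - y.mean()) ** 2)
    rss = resid @ resid
    r2 = 1.0 - rss / tss
    df_model = p - 1
    f = (tss - rss) / df_model / sigma2
    return beta, se, r2, f, df_model, df_resid


def quad_design(psd, dfa):
    return np.column_stack(
        [np.ones_like(psd), psd, psd**2, dfa, dfa**2]
    )


class TestQuadraticModel:
    def test_exact_quadratic_is_recovered(self, rng):
        dfa = rng.uniform(0.3, 1.7, 40)
        psd = rng.normal(-1, 0.5, 40)
        y = 2.0 - 3.0 * (dfa - 1.0) ** 2
        res = quadratic_model_test(y, psd, dfa)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)
        assert res.params["dfa^2"] == pytest.approx(-3.0, abs=1e-8)
        assert res.params["dfa"] == pytest.approx(6.0, abs=1e-8)
        assert res.params["psd"] == pytest.approx(0.0, abs=1e-8)

    def test_degrees_of_freedom_arithmetic(self, rng):
        n = 57
        res = quadratic_model_test(
            rng.standard_normal(n), rng.standard_normal(n), rng.standard_normal(n)
        )
        assert res.df_model == 4
        assert res.df_resid == 52
        assert res.nobs == 57

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 60))
            psd = rng.normal(-1, 0.6, n)
            dfa = rng.normal(1, 0.3, n)
            y = rng.standard_normal(n)
            res = quadratic_model_test(y, psd, dfa)
            beta, se, r2, f, dfm, dfr = ols_oracle(y, quad_design(psd, dfa))
            np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)
            np.testing.assert_allclose(res.bse.to_numpy(), se, atol=1e-8)
            assert res.rsquared == pytest.approx(r2, abs=1e-8)
            assert res.fvalue == pytest.approx(f, abs=1e-6)
            assert (res.df_model, res.df_resid) == (dfm, dfr)

    def test_type_one_error_rate_under_null(self):
        # all variables independent noise at the study's n: the overall F
        # should reject at the nominal 5% rate
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            res = quadratic_model_test(
                rng.standard_normal(57),
                rng.standard_normal(57),
                rng.standard_normal(57),
            )
            rejections += res.f_pvalue < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_confidence_intervals_cover_planted_coefficient(self):
        # planted quadratic models: the 95% CI of the dfa^2 term must
        # cover the truth in at least 90% of replicates
        rng = np.random.default_rng(77)
        for b2 in (-3.0, 0.0):
            covered = 0
            reps = 100
            for _ in range(reps):
                n = 200
                psd = rng.normal(-1, 0.5, n)
                dfa = rng.uniform(0.5, 1.5, n)
                y = 1.0 + 0.5 * dfa + b2 * dfa**2 + rng.normal(0, 0.5, n)
                res = InvertedUModel(y, psd, dfa).fit()
                lo, hi = res.conf_int.loc["dfa^2"]
                covered += lo <= b2 <= hi
            assert covered / reps >= 0.90

    def test_r2_invariant_under_affine_outcome_rescaling(self, rng):
        n = 50
        psd = rng.normal(-1, 0.5, n)
        dfa = rng.normal(1, 0.3, n)
        y = 1 + dfa + rng.standard_normal(n)
        r2 = quadratic_model_test(y, psd, dfa).rsquared
        r2_scaled = quadratic_model_test(10 * y - 4, psd, dfa).rsquared
        assert r2 == pytest.approx(r2_scaled, abs=1e-10)

    def test_collinearity_names_offending_term(self, rng):
        n = 30
        y = rng.standard_normal(n)
        dfa = rng.standard_normal(n)
        with pytest.raises(CollinearityError, match="psd"):
            quadratic_model_test(y, np.full(n, 2.0), dfa)

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            quadratic_model_test(
                rng.standard_normal(8), rng.standard_normal(8), rng.standard_normal(8)
            )

    def test_complete_case_analysis(self, rng):
        n = 30
        y = rng.standard_normal(n)
        psd = rng.standard_normal(n)
        dfa = rng.standard_normal(n)
        y[3] = np.nan
        res = quadratic_model_test(y, psd, dfa)
        assert res.nobs == n - 1

    def test_from_dataframe_and_summary(self, rng):
        n = 20
        table = pd.DataFrame(
            {
                "aut_creativity": rng.standard_normal(n) + 2,
                "psd_slope": rng.normal(-1, 0.4, n),
                "dfa_alpha": rng.normal(1, 0.2, n),
            }
        )
        res = InvertedUModel.from_dataframe(table).fit()
        text = res.summary()
        assert "dfa^2" in text and "R^2" in text
        report = res.to_dict()
        assert report["df"] == [4, n - 5]


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_test(x, x)[0] == pytest.approx(1.0)
        assert pearson_test(x, -x)[0] == pytest.approx(-1.0)

    def test_four_point_fixture_by_hand(self):
        # normal-equation arithmetic on (1,2),(2,1),(3,4),(4,3):
        # Sxy = 3, Sxx = Syy = 5 -> r = 0.6; t = 0.6*sqrt(2)/0.8, p = 0.4
        r, p, n = pearson_test([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert p == pytest.approx(0.4)
        assert n == 4

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(InvalidInputError):
            pearson_test([1.0, 2.0], [1.0, 2.0])


class TestRtSmdRegression:
    def test_two_point_input_is_saturated(self):
        res = rt_smd_regression([1.0, 2.0], [0.2, 0.6])
        assert res.rsquared == pytest.approx(1.0)
        assert np.isnan(res.f_pvalue)

    def test_recovers_planted_slope(self, rng):
        n = 60
        rt = rng.uniform(5, 50, n)
        smd = 0.3 + 0.004 * rt + rng.normal(0, 0.02, n)
        res = rt_smd_regression(rt, smd)
        assert res.params["mean_rt"] == pytest.approx(0.004, abs=0.002)
        assert res.pvalues["mean_rt"] < 0.001


class TestIcc2k:
    def test_identical_raters_agree_perfectly(self):
        col = np.array([1.0, 2, 3, 4, 5, 3])
        assert icc2k(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_hand_computed_six_item_table(self):
        # two-way ANOVA by hand: MSR = 3.883333, MSC = 0.083333,
        # MSE = 0.283333 -> ICC(2,k) = 0.935064935065
        R = [[1, 2], [2, 2], [3, 4], [4, 4], [5, 5], [5, 4]]
        assert icc2k(R) == pytest.approx(0.935064935065, abs=1e-9)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        R = rng.integers(1, 6, size=(12, 3)).astype(float)
        n, k = R.shape
        df = pd.DataFrame(
            {
                "item": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": R.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            df, targets="item", raters="rater", ratings="score"
        )
        want = float(ref.loc[ref["Type"] == "ICC(A,k)", "ICC"].iloc[0])
        assert icc2k(R) == pytest.approx(want, abs=1e-9)

    def test_independent_raters_average_near_zero(self):
        rng = np.random.default_rng(11)
        vals = [
            icc2k(rng.standard_normal((200, 2))) for _ in range(100)
        ]
        assert abs(np.mean(vals)) <= 0.1

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(4)
        R = rng.uniform(1, 5, (10, 3))
        assert icc2k(R) == pytest.approx(icc2k(R + 2.5), abs=1e-10)

    def test_missing_cells_rejected(self):
        R = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(InvalidInputError):
            icc2k(R)
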