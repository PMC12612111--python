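"""Subset enumeration, OLS fits, sign filter, ranking and final selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

import vibropredict as vp
from vibropredict.search import RankingEntry, _order_keys


class TestEnumerateSubsets:
    @pytest.mark.parametrize("k, count", [(1, 14), (3, 364), (4, 1001)])
    def test_counts(self, k, count):
        subsets = vp.enumerate_subsets(list("abcdefghijklmn"), k)
        assert len(subsets) == count
        assert len(set(subsets)) == count

    def test_three_and_four_term_search_space(self):
        terms = list(range(14))
        union = vp.enumerate_subsets(terms, 3) + vp.enumerate_subsets(terms, 4)
        assert len(union) == 1365 and len(set(union)) == 1365

    def test_order_is_lexicographic_and_deterministic(self):
        subsets = vp.enumerate_subsets(["a", "b", "c", "d"], 2)
        assert subsets == sorted(subsets)

    def test_out_of_range_size_rejected(self):
        with pytest.raises(ValueError):
            vp.enumerate_subsets(["a", "b"], 3)


class TestFitOls:
    def test_perfect_linear_relationship(self):
        x = np.arange(10, dtype=float)
        fit = vp.fit_ols(3.0 * x + 2.0, pd.DataFrame({"x": x}))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.mae == pytest.approx(0.0, abs=1e-10)

    def test_identity_line(self):
        fit = vp.fit_ols([1.0, 2.0, 3.0], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert fit.beta["const"] == pytest.approx(0.0, abs=1e-10)
        assert fit.beta["x"] == pytest.approx(1.0)

    def test_rmse_identity_with_residuals(self, study_frame):
        fit = vp.fit_ols(study_frame["wrs_65"], study_frame[["age", "bc_pta4"]])
        assert fit.rmse**2 * fit.nobs == pytest.approx(np.sum(fit.resid**2), abs=1e-9)
        assert fit.df2 == fit.nobs - len(fit.terms) - 1

    def test_f_statistic_closed_form(self):
        # R² = 0.51 with (3, 16) df: F = (0.51/3)/(0.49/16) ≈ 5.55,
        # matching the reported F(3,16) = 5.51 to the printed precision
        f = vp.f_from_r2(0.51, k=3, n=20)
        assert f == pytest.approx((0.51 / 3) / (0.49 / 16))
        assert f == pytest.approx(5.51, abs=0.05)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_normal_equations_oracle(self, seed):
        """On tiny instances OLS equals the explicit (XᵀX)⁻¹Xᵀy solution."""
        rng = np.random.default_rng(seed)
        n, k = rng.integers(4, 9), rng.integers(1, 3)
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
        y = rng.normal(size=n)
        fit = vp.fit_ols(y, X)
        A = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)

    def test_rank_deficiency_names_collinear_terms(self, study_frame):
        X = study_frame[["age"]].copy()
        X["age_twice"] = 2.0 * X["age"]
        with pytest.raises(vp.RankDeficientError, match="age"):
            vp.fit_ols(study_frame["wrs_65"], X)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            vp.fit_ols([1.0, 2.0], pd.DataFrame({"x": [1.0, 2.0]}))


class TestSignCoherence:
    def fit_for(self, betas):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, len(betas))), columns=list(betas))
        y = X.to_numpy() @ np.array(list(betas.values())) + 50.0
        return vp.fit_ols(y, X)

    def test_matching_signs(self):
        fit = self.fit_for({"age": -0.28, "wrs_max": 0.2})
        assert vp.sign_coherent(fit, {"age": -1, "wrs_max": 1})

    def test_mismatch_detected(self):
        fit = self.fit_for({"wrs_max": -0.1})
        assert not vp.sign_coherent(fit, {"wrs_max": 1})

    def test_zero_coefficient_matches_any_expectation(self):
        fit = self.fit_for({"a": 1.0, "b": 0.5})
        fit.beta["a"] = 0.0
        assert vp.sign_coherent(fit, {"a": -1, "b": 1})

    def test_zero_expectation_accepts_any_sign(self):
        fit = self.fit_for({"a": -1.0})
        assert vp.sign_coherent(fit, {"a": 0})

    def test_missing_expected_sign_is_an_error(self):
        fit = self.fit_for({"a": 1.0})
        with pytest.raises(KeyError):
            vp.sign_coherent(fit, {})


class TestRankModels:
    def make_fit(self, r2, sab, mae, sign=1):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        fit = vp.fit_ols(rng.normal(size=20) + 50, X)
        fit.r2, fit.mae = r2, mae
        fit.beta["x"] = sign * sab
        return fit

    def test_higher_r2_ranks_first(self):
        fits = [self.make_fit(0.4, 1.0, 2.0), self.make_fit(0.6, 1.0, 2.0)]
        ranked = vp.rank_models(fits, {"x": 1}, top=10)
        assert ranked[0].fit.r2 == 0.6

    def test_tie_broken_by_smaller_coefficient_sum(self):
        fits = [self.make_fit(0.5, 3.4, 2.0), self.make_fit(0.5, 1.2, 2.0)]
        ranked = vp.rank_models(fits, {"x": 1}, top=10)
        assert ranked[0].fit.sum_abs_beta == pytest.approx(1.2)

    def test_incoherent_models_never_outrank_coherent(self):
        fits = [self.make_fit(0.9, 1.0, 1.0, sign=-1), self.make_fit(0.2, 1.0, 1.0)]
        ranked = vp.rank_models(fits, {"x": 1}, top=10)
        assert [e.fit.r2 for e in ranked] == [0.2]

    def test_no_coherent_fit_warns_and_returns_empty(self):
        fits = [self.make_fit(0.5, 1.0, 1.0, sign=-1)]
        with pytest.warns(UserWarning, match="sign-coherent"):
            assert vp.rank_models(fits, {"x": 1}) == []

    def test_noise_search_returns_top_ten_per_size(self, no_warnings):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            {
                "age": rng.normal(50, 10, 20),
                "bc_pta4": rng.normal(30, 10, 20),
                "vib_pta4": rng.normal(40, 10, 20),
                "wrs_max": rng.normal(85, 10, 20),
                "wrs_65": np.clip(rng.normal(80, 9, 20), 0, 100),
            }
        )
        design = vp.build_terms(frame)
        y = frame["wrs_65"].to_numpy()
        expected = vp.expected_signs(design, y, base_signs={})
        for k in (3, 4):
            fits = [
                vp.fit_ols(y, design.subset(s))
                for s in vp.enumerate_subsets(design.term_names, k)
            ]
            assert len(vp.rank_models(fits, expected, top=10)) == 10


class TestRegularizedFit:
    def test_vanishing_penalty_approaches_ols(self, study_frame):
        X = study_frame[["age", "bc_pta4", "wrs_max"]]
        y = study_frame["wrs_65"]
        ols = vp.fit_ols(y, X)
        for method in ("lasso", "ridge", "elastic_net"):
            reg = vp.regularized_fit(y, X, method, alphas=[1e-10])
            assert float((reg.beta - ols.beta).abs().max()) < 1e-3, method

    def test_strong_lasso_zeroes_all_coefficients(self, study_frame):
        X = study_frame[["age", "bc_pta4", "wrs_max"]]
        reg = vp.regularized_fit(study_frame["wrs_65"], X, "lasso", alphas=[1e6])
        assert float(reg.beta.drop("const").abs().max()) == 0.0

    def test_ridge_recovers_planted_coefficient(self, planted_frame_200):
        X = planted_frame_200[["age", "bc_pta4", "wrs_max"]]
        reg = vp.regularized_fit(planted_frame_200["wrs_65"], X, "ridge", seed=0)
        assert reg.beta["age"] == pytest.approx(-0.2809, abs=0.1)

    def test_empty_grid_rejected(self, study_frame):
        with pytest.raises(ValueError, match="empty"):
            vp.regularized_fit(study_frame["wrs_65"], study_frame[["age"]], "lasso", alphas=[])

    def test_unknown_method_rejected(self, study_frame):
        with pytest.raises(ValueError, match="unknown method"):
            vp.regularized_fit(study_frame["wrs_65"], study_frame[["age"]], "ols")


class TestSelectFinal:
    def entry(self, y, predicted, sign_ok=True):
        X = pd.DataFrame({"x": np.linspace(-1, 1, len(y))})
        fit = vp.fit_ols(y, X)
        res = vp.SigmoidLinearModel(np.asarray(y, float), X).fit()
        # overwrite the pipeline predictions with the scripted ones
        res.fittedvalues = np.asarray(predicted, dtype=float)
        res.resid = np.asarray(y, float) - res.fittedvalues
        res.mae = float(np.mean(np.abs(res.resid)))
        res.rsquared = 1 - np.sum(res.resid**2) / np.sum((y - np.mean(y)) ** 2)
        return RankingEntry(fit=fit, sign_ok=sign_ok, results=res)

    def test_single_candidate_selected(self):
        y = [60.0, 70, 80, 90, 75, 65]
        e = self.entry(y, [62.0, 69, 81, 84, 74, 66])
        assert vp.select_final([e], y) is e

    def test_dominant_candidate_wins_regardless_of_r2(self):
        y = np.array([60.0, 70, 80, 90, 75, 65])
        good = self.entry(y, y + np.array([1.0, -1, 1, -8, 1, -1]))
        bad = self.entry(y, y + np.array([2.0, -2, 2, -12, 2, -2]))
        winner = vp.select_final([good, bad], y)
        assert winner is good
        assert winner.avg_outlier_rank < bad.avg_outlier_rank

    def test_no_outliers_falls_back_to_r2(self):
        y = np.array([60.0, 70, 80, 90, 75, 65])
        perfect = self.entry(y, y.copy())
        with pytest.warns(UserWarning, match="falling back"):
            assert vp.select_final([perfect], y) is perfect

    def test_supplied_outlier_ids_respected(self):
        y = np.array([60.0, 70, 80, 90, 75, 65])
        a = self.entry(y, y + np.array([0.0, 0, 0, -10, 0, 0]))
        b = self.entry(y, y + np.array([5.0, 5, 5, -2, 5, 5]))
        winner = vp.select_final([a, b], y, outlier_ids=[3])
        assert winner is b  # b is better on the only scored case


def test_full_search_winner_is_coherent_and_among_finalists(study_frame, no_warnings):
    res = vp.ModelSearch(study_frame, seed=0).fit()
    assert res.n_fits == {3: 364, 4: 1001}
    assert res.selected.sign_ok
    finalist_terms = {e.terms for entries in res.top_linear.values() for e in entries}
    assert res.selected.terms in finalist_terms
    assert res.ranking["selected"].sum() == 1
    assert set(res.ranking.columns) >= {
        "terms", "R2", "RMSE", "MAE", "r", "F", "p", "sum_abs_beta",
        "sign_ok", "optimization", "avg_outlier_rank",
    }
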