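"""Logistic output transform, published constants and the Model/Results API."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vibropredict as vp
from vibropredict.model import load_model_file

PUB = vp.PUBLISHED_MODEL


class TestSigmoidPredict:
    def test_midpoint_returns_exactly_fifty(self):
        assert vp.sigmoid_predict(57.2941, PUB.sigmoid) == pytest.approx(50.0)

    def test_saturates_at_the_ceiling(self):
        assert vp.sigmoid_predict(1e6, PUB.sigmoid) == pytest.approx(100.0)
        assert vp.sigmoid_predict(-1e6, PUB.sigmoid) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_cohort_mean_linear_predictor(self):
        # direct evaluation of the printed formula at x = 81.51
        assert vp.sigmoid_predict(81.51, PUB.sigmoid) == pytest.approx(82.1, abs=0.05)

    def test_strictly_increasing(self):
        x = np.linspace(0, 120, 200)
        y = vp.sigmoid_predict(x, PUB.sigmoid)
        assert np.all(np.diff(y) > 0)

    @given(d=st.floats(0, 200, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_about_the_midpoint(self, d):
        c = PUB.sigmoid.midpoint
        total = vp.sigmoid_predict(c + d, PUB.sigmoid) + vp.sigmoid_predict(c - d, PUB.sigmoid)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            vp.SigmoidParams(slope=0.0, midpoint=50.0)


class TestLinearPredictor:
    def test_published_at_cohort_means(self):
        x = vp.linear_predictor(47.0, 28.0, 88.5, PUB.beta)
        assert x == pytest.approx(81.51, abs=0.01)

    def test_intercept_only(self):
        beta = {"const": 10.0, "age": 0.0, "bc_pta4": 0.0, "wrs_max": 0.0}
        assert vp.linear_predictor(50.0, 30.0, 90.0, beta) == pytest.approx(10.0)

    def test_age_effect_per_decade(self):
        x1 = vp.linear_predictor(40.0, 28.0, 88.5, PUB.beta)
        x2 = vp.linear_predictor(50.0, 28.0, 88.5, PUB.beta)
        assert x1 - x2 == pytest.approx(2.809)

    def test_out_of_range_input_warns_not_fails(self):
        with pytest.warns(UserWarning, match="extrapolation"):
            vp.linear_predictor(90.0, 28.0, 88.5, PUB.beta)


class TestPublishedModel:
    def test_internal_consistency_at_cohort_means(self):
        """The packaged constants evaluated at the cohort-mean inputs land on
        the observed mean outcome (81.5 %) to within 1.5 points."""
        pred = PUB.predict(age=47.0, bc_pta4=28.0, wrs_max=88.5)
        assert pred == pytest.approx(81.5, abs=1.5)

    def test_monotone_in_each_predictor(self):
        base = PUB.predict(age=47.0, bc_pta4=28.0, wrs_max=88.5)
        assert PUB.predict(age=57.0, bc_pta4=28.0, wrs_max=88.5) < base
        assert PUB.predict(age=47.0, bc_pta4=38.0, wrs_max=88.5) < base
        assert PUB.predict(age=47.0, bc_pta4=28.0, wrs_max=78.5) < base

    def test_dataframe_prediction(self, study_frame):
        preds = PUB.predict(data=study_frame)
        assert len(preds) == len(study_frame)
        assert np.all((preds > 0) & (preds < 100))


class TestFitSigmoid:
    def x_grid(self):
        return np.linspace(35, 85, 20)

    def test_noiseless_parameter_recovery(self):
        truth = vp.SigmoidParams(slope=0.063, midpoint=57.3)
        x = self.x_grid()
        params = vp.fit_sigmoid(x, vp.sigmoid_predict(x, truth))
        assert params.slope == pytest.approx(0.063, abs=0.005)
        assert params.midpoint == pytest.approx(57.3, abs=0.5)

    def test_noisy_recovery_within_twenty_percent(self):
        truth = vp.SigmoidParams(slope=0.063, midpoint=57.3)
        x = self.x_grid()
        clean = vp.sigmoid_predict(x, truth)
        slopes, mids = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.clip(clean + rng.normal(0, 3, size=len(x)), 0, 100)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = vp.fit_sigmoid(x, y)
            slopes.append(p.slope)
            mids.append(p.midpoint)
        assert np.mean(slopes) == pytest.approx(0.063, rel=0.2)
        assert np.mean(mids) == pytest.approx(57.3, rel=0.2)

    def test_residual_zero_at_midpoint_for_any_slope(self):
        for a in (0.01, 0.1, 0.9):
            y50 = vp.sigmoid_predict(60.0, vp.SigmoidParams(a, 60.0))
            assert y50 == pytest.approx(50.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            vp.fit_sigmoid([1.0, 2.0], [10.0, 20.0])
        with pytest.raises(ValueError, match="unidentifiable"):
            vp.fit_sigmoid([1.0, 2.0, 3.0], [50.0, 50.0, 50.0])
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            vp.fit_sigmoid([1.0, 2.0, 3.0], [10.0, 50.0, 120.0])


class TestModelResults:
    def test_fit_and_predict_round_trip(self, planted_frame_200):
        mdl = vp.SigmoidLinearModel.from_dataframe(
            planted_frame_200, terms=["age", "bc_pta4", "wrs_max"]
        )
        res = mdl.fit()
        np.testing.assert_allclose(
            res.predict(planted_frame_200), res.fittedvalues, atol=1e-9
        )
        assert res.df_resid == res.nobs - 4
        assert 0.0 < res.rsquared <= 1.0

    def test_standardized_and_raw_fits_predict_identically(self, study_frame):
        """The z-transform is affine: an all-linear subset spans the same
        prediction space standardized or raw."""
        design = vp.build_terms(study_frame)
        y = study_frame["wrs_65"].to_numpy()
        std = vp.SigmoidLinearModel(y, design.subset(["age", "bc_pta4", "wrs_max"])).fit()
        raw = vp.SigmoidLinearModel.from_dataframe(
            study_frame, terms=["age", "bc_pta4", "wrs_max"]
        ).fit()
        np.testing.assert_allclose(std.fittedvalues, raw.fittedvalues, atol=1e-6)
        assert std.rsquared == pytest.approx(raw.rsquared, abs=1e-8)

    def test_fvalue_matches_closed_form(self, study_frame):
        res = vp.SigmoidLinearModel.from_dataframe(
            study_frame, terms=["age", "bc_pta4", "wrs_max"]
        ).fit()
        assert res.fvalue == pytest.approx(
            vp.f_from_r2(res.rsquared, res.df_model, res.nobs)
        )

    def test_summary_lists_terms_and_sigmoid(self, study_frame):
        res = vp.SigmoidLinearModel.from_dataframe(
            study_frame, terms=["age", "bc_pta4", "wrs_max"]
        ).fit()
        text = res.summary()
        for token in ("age", "bc_pta4", "wrs_max", "sigmoid", "R2"):
            assert token in text

    def test_save_load_round_trip(self, study_frame, tmp_path):
        res = vp.SigmoidLinearModel.from_dataframe(
            study_frame, terms=["age", "bc_pta4", "wrs_max"]
        ).fit()
        path = tmp_path / "model.txt"
        res.save(path)
        beta, sig = load_model_file(path)
        assert beta["age"] == pytest.approx(res.params["age"])
        assert sig.slope == pytest.approx(res.sigmoid.slope)
        assert sig.midpoint == pytest.approx(res.sigmoid.midpoint)
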