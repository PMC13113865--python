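"""FNR sweep, optimum selection, observation assembly, polynomial calibration."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from psmcfnr import (
    CalibrationModel,
    CoverageObservation,
    FNRCalibrator,
    SampleMeta,
    ScaledTrajectory,
    TimeGrid,
    assemble_observations,
    fit_polynomial,
    predict_fnr,
    select_degree,
    select_optimal_fnr,
    sweep_fnr,
)
from psmcfnr.calibration import SweepResult, _fnr_candidates


def make_sweep_result(fnr, frechet, hausdorff=None, coverage=10.0):
    records = pd.DataFrame(
        {
            "fnr": fnr,
            "hausdorff": hausdorff if hausdorff is not None else frechet,
            "frechet": frechet,
            "sse": np.zeros(len(fnr)),
        }
    )
    opt_f = records.loc[records["frechet"].idxmin(), "fnr"]
    opt_h = records.loc[records["hausdorff"].idxmin(), "fnr"]
    return SweepResult(records, opt_f, opt_h, 0.0, 0.0, TimeGrid(), "s", coverage)


class TestCandidateGrid:
    def test_default_sweep_has_100_candidates(self):
        c = _fnr_candidates(0.0, 0.99, 0.01)
        assert c.size == 100
        assert c[0] == 0.0
        assert c[-1] == 0.99

    def test_candidates_are_exact_decimals(self):
        c = _fnr_candidates(0.0, 0.99, 0.01)
        assert 0.30 in c
        assert 0.07 in c


class TestSweepFnr:
    def test_identity_query_optimum_is_zero(self, bottleneck_trajectory):
        res = sweep_fnr(bottleneck_trajectory, bottleneck_trajectory)
        assert len(res.records) == 100
        assert res.optimal_fnr_frechet == 0.0
        assert res.records["frechet"].min() == 0.0
        assert res.sse_uncorrected == 0.0

    def test_recovers_on_grid_distortion_exactly(self, bottleneck_trajectory):
        f_true = 0.30
        query = ScaledTrajectory(
            bottleneck_trajectory.times * (1 - f_true),
            bottleneck_trajectory.ne * (1 - f_true),
            SampleMeta("q", 10.0),
        )
        res = sweep_fnr(bottleneck_trajectory, query)
        assert res.optimal_fnr_frechet == f_true
        assert res.optimal_fnr_hausdorff == f_true
        at_opt = res.records.loc[res.records["fnr"] == f_true, "frechet"].iloc[0]
        assert at_opt < 1e-9

    def test_sse_fields(self, bottleneck_trajectory):
        query = ScaledTrajectory(
            bottleneck_trajectory.times * 0.8,
            bottleneck_trajectory.ne * 0.8,
            SampleMeta("q", 10.0),
        )
        res = sweep_fnr(bottleneck_trajectory, query)
        assert res.sse_at_optimum <= res.sse_uncorrected
        assert res.log10_sse_reduction > 0

    def test_step_and_bounds_validation(self, bottleneck_trajectory):
        with pytest.raises(ValueError):
            sweep_fnr(bottleneck_trajectory, bottleneck_trajectory, step=0.0)
        with pytest.raises(ValueError):
            sweep_fnr(bottleneck_trajectory, bottleneck_trajectory, fnr_max=1.0)


class TestSelectOptimalFnr:
    def test_unique_minimum(self):
        fnr = np.round(np.arange(0, 1.0, 0.01), 10)[:100]
        frechet = np.abs(fnr - 0.42)
        res = make_sweep_result(fnr, frechet)
        assert select_optimal_fnr(res) == pytest.approx(0.42)

    def test_tie_breaks_to_smallest_fnr(self):
        fnr = np.array([0.0, 0.1, 0.2])
        res = make_sweep_result(fnr, np.ones(3))
        assert select_optimal_fnr(res) == 0.0

    def test_metric_specific_argmin(self):
        fnr = np.array([0.0, 0.1, 0.2])
        res = make_sweep_result(
            fnr, frechet=np.array([1.0, 0.1, 1.0]), hausdorff=np.array([1.0, 1.0, 0.1])
        )
        assert select_optimal_fnr(res, "frechet") == pytest.approx(0.1)
        assert select_optimal_fnr(res, "hausdorff") == pytest.approx(0.2)
        with pytest.raises(ValueError, match="metric"):
            select_optimal_fnr(res, "euclid")


class TestAssembleObservations:
    def test_reference_contributes_anchor(self):
        sweeps = {c: make_sweep_result(np.array([0.0, 0.1]), np.array([1.0, 0.5]), coverage=c)
                  for c in (5.0, 10.0)}
        obs = assemble_observations(sweeps, anchor_coverages=[20.0])
        anchors = [o for o in obs if o.source == "anchor"]
        assert [(a.coverage, a.optimal_fnr) for a in anchors] == [(20.0, 0.0)]
        assert len(obs) == 3

    def test_swept_sample_at_threshold_becomes_anchor(self):
        sweeps = {c: make_sweep_result(np.array([0.0, 0.1]), np.array([1.0, 0.5]), coverage=c)
                  for c in (5.0, 10.0, 15.0)}
        obs = assemble_observations(sweeps)
        at15 = [o for o in obs if o.coverage == 15.0]
        assert at15 == [CoverageObservation(15.0, 0.0, "anchor", "s")]

    def test_no_high_coverage_sample_means_no_anchor(self):
        sweeps = {c: make_sweep_result(np.array([0.0, 0.1]), np.array([1.0, 0.5]), coverage=c)
                  for c in (5.0, 8.0, 10.0)}
        obs = assemble_observations(sweeps)
        assert all(o.source == "swept" for o in obs)

    def test_too_few_points_rejected(self):
        sweeps = {5.0: make_sweep_result(np.array([0.0, 0.1]), np.array([1.0, 0.5]))}
        with pytest.raises(ValueError, match="insufficient points"):
            assemble_observations(sweeps)


class TestFitPolynomial:
    def test_recovers_exact_quadratic(self):
        coefs = (0.9, -0.1, 0.002)
        cov = np.arange(5.0, 12.0)  # law stays within [0, 0.99] here
        fnr = coefs[0] + coefs[1] * cov + coefs[2] * cov**2
        obs = [CoverageObservation(c, f) for c, f in zip(cov, fnr)]
        model = fit_polynomial(obs, degree=2)
        np.testing.assert_allclose(model.coefficients, coefs, atol=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_constant_data_degenerate_r2_convention(self):
        obs = [CoverageObservation(c, 0.2) for c in (5.0, 8.0, 11.0, 14.0)]
        model = fit_polynomial(obs, degree=1)
        assert model.coefficients[1] == pytest.approx(0.0, abs=1e-12)
        assert model.coefficients[0] == pytest.approx(0.2)
        assert model.r_squared == 1.0  # SS_tot = 0 with zero residuals

    def test_three_points_degree_two_interpolates(self):
        obs = [CoverageObservation(5.0, 0.5), CoverageObservation(10.0, 0.1),
               CoverageObservation(15.0, 0.0)]
        model = fit_polynomial(obs, degree=2)
        np.testing.assert_allclose(model.predict([5.0, 10.0, 15.0]), [0.5, 0.1, 0.0], atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        obs = [CoverageObservation(10.0, f) for f in (0.1, 0.2, 0.3)]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_polynomial(obs, degree=1)


class TestSelectDegree:
    def test_linear_data_prefers_degree_one(self):
        cov = np.arange(5.0, 16.0)
        obs = [CoverageObservation(c, 0.75 - 0.05 * c) for c in cov]
        model = select_degree(obs)
        assert model.degree == 1

    def test_quadratic_data_with_noise_selects_degree_two(self):
        rng = np.random.default_rng(2024)
        cov = np.arange(5.0, 16.0)
        fnr = 0.6 * (15.0 - cov) ** 2 / 15.0**2
        fnr = np.clip(fnr + rng.normal(0, 0.004, cov.size), 0.0, 0.99)
        obs = [CoverageObservation(c, f) for c, f in zip(cov, fnr)]
        model = select_degree(obs)
        assert model.degree == 2

    def test_strongly_cubic_data_selects_degree_three(self):
        cov = np.arange(5.0, 16.0)
        centered = (cov - 10.0) / 5.0
        fnr = np.clip(0.4 + 0.3 * centered**3, 0.0, 0.99)
        obs = [CoverageObservation(c, f) for c, f in zip(cov, fnr)]
        model = select_degree(obs)
        assert model.degree == 3


class TestPredictFnr:
    def model(self):
        return CalibrationModel(2, (0.9, -0.1, 0.002), 1.0)

    def test_polynomial_arithmetic(self):
        assert predict_fnr(self.model(), 10.0)[0] == pytest.approx(0.9 - 1.0 + 0.2)

    def test_clamps_negative_to_zero(self):
        model = CalibrationModel(1, (0.15, -0.01), 1.0)
        assert predict_fnr(model, 18.0)[0] == 0.0

    def test_clamps_above_sweep_maximum(self):
        model = CalibrationModel(1, (1.5, -0.01), 1.0)
        assert predict_fnr(model, 5.0)[0] == 0.99

    def test_rejects_nonpositive_coverage(self):
        with pytest.raises(ValueError, match="coverage"):
            predict_fnr(self.model(), -3.0)


class TestFNRCalibratorEstimator:
    def test_sklearn_params_round_trip(self):
        cal = FNRCalibrator(degree=2, parsimony_tol=0.01)
        cal2 = clone(cal)
        assert cal2.get_params()["degree"] == 2
        assert cal2.get_params()["parsimony_tol"] == 0.01

    def test_fit_predict_shapes_and_attrs(self):
        cov = np.arange(5.0, 16.0)[:, None]
        fnr = 0.6 * (15.0 - cov[:, 0]) ** 2 / 225.0
        cal = FNRCalibrator().fit(cov, fnr)
        assert cal.degree_ == 2
        assert cal.coef_.shape == (3,)
        assert cal.r_squared_ > 0.999
        pred = cal.predict(np.array([[7.5], [15.0]]))
        assert pred.shape == (2,)
        assert pred[1] == pytest.approx(0.0, abs=1e-9)

    def test_score_is_r2_like(self):
        cov = np.arange(5.0, 16.0)[:, None]
        fnr = 0.5 - 0.03 * cov[:, 0]
        cal = FNRCalibrator().fit(cov, fnr)
        assert cal.score(cov, fnr) == pytest.approx(1.0, abs=1e-9)


class TestCalibrationModelReport:
    def test_report_round_trip(self, tmp_path):
        model = CalibrationModel(2, (0.9, -0.1, 0.002), 0.995, "hausdorff",
                                 TimeGrid(60, 5e4, 1.5e6), 15.0)
        path = tmp_path / "model.txt"
        model.write_report(path)
        back = CalibrationModel.read_report(path)
        assert back == model

    def test_malformed_report_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("degree\ttwo\n")
        with pytest.raises(ValueError, match="malformed"):
            CalibrationModel.read_report(path)
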