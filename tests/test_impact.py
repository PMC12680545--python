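"""Impact-force model representation, fitting, aggregation and recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femrisk.impact import (
    CONTROL_STT_MEAN_SD,
    GRAVITY,
    ImpactModelSet,
    LinearImpactModel,
    Metric,
    SummaryPoint,
    Unit,
    aggregate_models,
    as_printed,
    evaluate_model,
    fit_points,
    max_impact_force,
    model_set_from_json,
    model_set_to_json,
    recover_from_mean_sd,
    recover_from_two_points,
    table_reconciled,
)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


def _ols_oracle(points):
    """Closed-form normal-equations OLS, independent of the implementation."""
    pts = np.asarray(points, float)
    X = np.column_stack([pts[:, 0], np.ones(len(pts))])
    beta = np.linalg.solve(X.T @ X, X.T @ pts[:, 1])
    return float(beta[0]), float(beta[1])


class TestEvaluate:
    def test_published_stt_model_at_origin(self):
        model = as_printed().models[Metric.STT]
        assert model.evaluate(0.0) == pytest.approx(7.10)

    @given(slope=finite, intercept=finite)
    @settings(max_examples=50, deadline=None)
    def test_any_model_at_origin_returns_intercept(self, slope, intercept):
        model = LinearImpactModel(Metric.AGE, slope, intercept, Unit.YEARS)
        assert model.evaluate(0.0) == intercept

    def test_reconciled_age_model_matches_published_fracture_median(self):
        model = table_reconciled().models[Metric.AGE]
        assert model.evaluate(63.5) == pytest.approx(3.50, abs=0.01)

    def test_unit_mismatch_rejected(self):
        model = as_printed().models[Metric.WEIGHT]  # expects newtons
        with pytest.raises(ValueError, match="unit|expects"):
            model.evaluate(60.0, unit=Unit.KG)

    def test_non_finite_input_rejected(self):
        model = as_printed().models[Metric.AGE]
        with pytest.raises(ValueError):
            model.evaluate(float("nan"))

    @given(x1=finite, x2=finite)
    @settings(max_examples=50, deadline=None)
    def test_exact_linearity(self, x1, x2):
        model = LinearImpactModel(Metric.STT, -0.0723, 7.10, Unit.MM)
        lhs = model.evaluate(x1 + x2) - model.evaluate(x1) - model.evaluate(x2)
        assert lhs + model.intercept == pytest.approx(0.0, abs=1e-6)


class TestFitPoints:
    @pytest.mark.parametrize("points,slope,intercept", [
        ([(0, 1), (1, 3)], 2.0, 1.0),
        ([(0, 0), (1, 1), (2, 2)], 1.0, 0.0),
    ])
    def test_exact_on_collinear_points(self, points, slope, intercept):
        model = fit_points(Metric.AGE, points)
        assert model.slope == pytest.approx(slope, abs=1e-12)
        assert model.intercept == pytest.approx(intercept, abs=1e-12)
        assert model.provenance == "fitted"

    def test_recovers_noisy_line_and_matches_normal_equations(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 50)
        y = 4.0 * x + 2.0 + rng.normal(0, 0.5, 50)
        points = list(zip(x, y))
        model = fit_points(Metric.WEIGHT, points, metric_unit=Unit.KG)
        slope_o, intercept_o = _ols_oracle(points)
        assert model.slope == pytest.approx(slope_o, rel=1e-10)
        assert model.intercept == pytest.approx(intercept_o, rel=1e-10)
        # true parameters recovered within ~3 standard errors
        resid = y - (model.slope * x + model.intercept)
        se = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
        assert abs(model.slope - 4.0) < 3 * se

    @given(st.lists(st.tuples(finite, finite), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_normal_equations_oracle(self, points):
        xs = [p[0] for p in points]
        if max(xs) - min(xs) < 1e-3:
            return
        gram = np.array([[sum(x * x for x in xs), sum(xs)],
                         [sum(xs), len(xs)]])
        if np.linalg.cond(gram) > 1e10:
            return
        model = fit_points(Metric.AGE, points)
        slope_o, intercept_o = _ols_oracle(points)
        assert model.slope == pytest.approx(slope_o, rel=1e-6, abs=1e-6)
        assert model.intercept == pytest.approx(intercept_o, rel=1e-6, abs=1e-6)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_points(Metric.AGE, [(1.0, 2.0), (1.0, 3.0)])


class TestAggregate:
    def test_single_model_is_identity(self):
        m = LinearImpactModel(Metric.HEIGHT, 4.55, -2.72, Unit.M)
        agg = aggregate_models([m])
        assert (agg.slope, agg.intercept) == (m.slope, m.intercept)
        assert agg.provenance == "aggregated"

    def test_unweighted_mean(self):
        models = [LinearImpactModel(Metric.AGE, 1.0, 0.0, Unit.YEARS),
                  LinearImpactModel(Metric.AGE, 3.0, 2.0, Unit.YEARS)]
        agg = aggregate_models(models)
        assert agg.slope == pytest.approx(2.0)
        assert agg.intercept == pytest.approx(1.0)

    def test_weighted_mean(self):
        models = [LinearImpactModel(Metric.AGE, 1.0, 0.0, Unit.YEARS),
                  LinearImpactModel(Metric.AGE, 3.0, 2.0, Unit.YEARS)]
        agg = aggregate_models(models, weights=[3, 1])
        assert agg.slope == pytest.approx(1.5)

    def test_equal_weights_match_unweighted(self):
        models = [LinearImpactModel(Metric.AGE, s, i, Unit.YEARS)
                  for s, i in [(-0.1, 10.0), (-0.06, 7.7), (-0.08, 9.0)]]
        a = aggregate_models(models)
        b = aggregate_models(models, weights=[2, 2, 2])
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept == pytest.approx(b.intercept)

    def test_mixed_metrics_and_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_models([])
        with pytest.raises(ValueError, match="share"):
            aggregate_models([
                LinearImpactModel(Metric.AGE, 1, 0, Unit.YEARS),
                LinearImpactModel(Metric.STT, 1, 0, Unit.MM),
            ])


class TestRecovery:
    def test_age_model_from_control_quartiles(self):
        model = recover_from_two_points(
            SummaryPoint(Metric.AGE, 54.0, 4.12, "quartile"),
            SummaryPoint(Metric.AGE, 68.8, 3.15, "quartile"))
        assert model.slope == pytest.approx(-0.97 / 14.8, rel=1e-9)
        assert model.intercept == pytest.approx(7.659, abs=1e-3)
        assert model.provenance == "table_reconciled"

    def test_weight_model_from_control_quartiles(self):
        model = recover_from_two_points(
            SummaryPoint(Metric.WEIGHT, 47.0, 3.87, "quartile"),
            SummaryPoint(Metric.WEIGHT, 60.1, 4.14, "quartile"))
        assert model.slope == pytest.approx(0.02061, abs=1e-5)
        assert model.intercept == pytest.approx(2.9013, abs=1e-4)

    def test_flat_line(self):
        model = recover_from_two_points(
            SummaryPoint(Metric.AGE, 0.0, 5.0), SummaryPoint(Metric.AGE, 1.0, 5.0))
        assert model.slope == 0.0
        assert model.intercept == 5.0

    @given(x1=st.floats(0, 100), x2=st.floats(0, 100),
           f1=st.floats(0.1, 10), f2=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_two_point_recovery_reproduces_inputs_exactly(self, x1, x2, f1, f2):
        if abs(x1 - x2) < 1e-6:
            return
        p1 = SummaryPoint(Metric.AGE, x1, f1)
        p2 = SummaryPoint(Metric.AGE, x2, f2)
        model = recover_from_two_points(p1, p2)
        assert evaluate_model(model, x1) == pytest.approx(f1, abs=1e-9)
        assert evaluate_model(model, x2) == pytest.approx(f2, abs=1e-9)

    def test_identical_x_rejected(self):
        p = SummaryPoint(Metric.AGE, 60.0, 3.5)
        with pytest.raises(ValueError, match="identical"):
            recover_from_two_points(p, p)

    def test_stt_model_from_control_mean_sd(self):
        model = recover_from_mean_sd(CONTROL_STT_MEAN_SD, slope_sign=-1)
        assert model.slope == pytest.approx(-0.078815, abs=1e-6)
        assert model.intercept == pytest.approx(7.1234, abs=1e-3)

    def test_sd_propagation_matches_published_fracture_sd(self):
        model = recover_from_mean_sd(CONTROL_STT_MEAN_SD, slope_sign=-1)
        assert abs(model.slope) * 7.10 == pytest.approx(0.560, abs=0.005)

    def test_equal_sds_unit_slope(self):
        p = SummaryPoint(Metric.STT, 1.0, 1.0, "mean", sd_pair=(2.0, 2.0))
        model = recover_from_mean_sd(p, slope_sign=+1)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0)

    def test_missing_sd_pair_rejected(self):
        p = SummaryPoint(Metric.STT, 1.0, 1.0, "mean")
        with pytest.raises(ValueError, match="sd_pair"):
            recover_from_mean_sd(p, slope_sign=-1)


class TestMaxImpactForce:
    def test_reconciled_set_on_control_median_subject(self):
        metrics = {"age": 64.0, "weight": 52.4, "height": 1.60, "stt": 34.3}
        model_set = table_reconciled()
        forces = model_set.per_metric_forces(metrics)
        assert forces[Metric.AGE] == pytest.approx(3.46, abs=0.01)
        assert forces[Metric.WEIGHT] == pytest.approx(3.98, abs=0.01)
        assert forces[Metric.HEIGHT] == pytest.approx(4.58, abs=0.01)
        assert forces[Metric.STT] == pytest.approx(4.42, abs=0.01)
        force, metric = max_impact_force(model_set, metrics)
        assert metric is Metric.HEIGHT
        assert force == pytest.approx(4.58, abs=0.01)

    def test_single_available_metric(self):
        model_set = ImpactModelSet.from_models(
            "one", [LinearImpactModel(Metric.STT, -0.0723, 7.10, Unit.MM)])
        force, metric = max_impact_force(model_set, {"stt": 10.0})
        assert metric is Metric.STT
        assert force == pytest.approx(7.10 - 0.723)

    def test_tie_breaks_to_earlier_metric(self):
        model_set = ImpactModelSet.from_models("tie", [
            LinearImpactModel(Metric.AGE, 0.0, 5.0, Unit.YEARS),
            LinearImpactModel(Metric.HEIGHT, 0.0, 5.0, Unit.M),
        ])
        _, metric = max_impact_force(model_set, {"age": 70.0, "height": 1.6})
        assert metric is Metric.AGE

    def test_no_overlapping_metric_rejected(self):
        model_set = ImpactModelSet.from_models(
            "one", [LinearImpactModel(Metric.STT, -0.07, 7.0, Unit.MM)])
        with pytest.raises(ValueError, match="no metric"):
            max_impact_force(model_set, {"age": 70.0})

    @given(age=st.floats(50, 90), weight=st.floats(35, 100),
           height=st.floats(1.3, 1.9), stt=st.floats(2, 60))
    @settings(max_examples=50, deadline=None)
    def test_max_dominates_every_model(self, age, weight, height, stt):
        metrics = {"age": age, "weight": weight, "height": height, "stt": stt}
        model_set = table_reconciled()
        force, _ = max_impact_force(model_set, metrics)
        for f in model_set.per_metric_forces(metrics).values():
            assert force >= f - 1e-12

    def test_as_printed_weight_model_takes_newtons(self):
        model_set = as_printed()
        forces = model_set.per_metric_forces({"weight": 52.4})
        expected = 0.00756 * 52.4 * GRAVITY + 0.00555
        assert forces[Metric.WEIGHT] == pytest.approx(expected)


class TestReconciliationProperty:
    """The reconciled models reproduce all published force summaries."""

    @pytest.mark.parametrize("age,expected", [
        (64.0, 3.46), (54.0, 4.12), (68.8, 3.15),   # control med [IQR]
        (63.5, 3.50), (68.8, 3.15), (53.5, 4.15),   # fracture med [IQR]
    ])
    def test_age_summaries(self, age, expected):
        model = table_reconciled().models[Metric.AGE]
        assert model.evaluate(age) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("weight,expected", [
        (52.4, 3.98), (47.0, 3.87), (60.1, 4.14),
        (56.2, 4.06), (50.2, 3.93), (65.8, 4.26),
    ])
    def test_weight_summaries(self, weight, expected):
        model = table_reconciled().models[Metric.WEIGHT]
        assert model.evaluate(weight) == pytest.approx(expected, abs=0.01)

    def test_stt_fracture_mean(self):
        model = table_reconciled().models[Metric.STT]
        assert model.evaluate(22.6) == pytest.approx(5.340, abs=0.01)


class TestSerialisation:
    def test_model_set_json_round_trip(self, tmp_path):
        path = tmp_path / "models.json"
        original = table_reconciled()
        model_set_to_json(original, path)
        loaded = model_set_from_json(path)
        assert loaded.set_id == original.set_id
        for metric, model in original.models.items():
            assert loaded.models[metric].slope == model.slope
            assert loaded.models[metric].intercept == model.intercept

    def test_literature_csv_loading_and_aggregation(self, tmp_path):
        models_csv = tmp_path / "studies.csv"
        points_csv = tmp_path / "points.csv"
        models_csv.write_text(
            "metric,label,n_samples,slope,intercept,metric_unit\n"
            "age,study-a,12,-0.10,9.0,years\n"
            "age,study-b,14,,,\n")
        points_csv.write_text(
            "metric,label,x,F\n"
            "age,study-b,50,5.0\nage,study-b,70,4.0\n")
        from femrisk.impact import aggregate_studies, load_literature_studies
        studies = load_literature_studies(models_csv, points_csv)
        assert len(studies) == 2
        agg = aggregate_studies(studies, Metric.AGE)
        # study-b fit: slope -0.05, intercept 7.5; mean with (-0.10, 9.0)
        assert agg.slope == pytest.approx((-0.10 - 0.05) / 2)
        assert agg.intercept == pytest.approx((9.0 + 7.5) / 2)
        weighted = aggregate_studies(studies, Metric.AGE, weighted=True)
        assert weighted.slope == pytest.approx((12 * -0.10 + 14 * -0.05) / 26)
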