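import numpy as np
import pandas as pd
import pytest

from urbansami.exceptions import DegenerateDataError
from urbansami.forecast import (
    ForecastModel,
    average_models,
    compare_predicted_empirical,
    cross_correlation_matrix,
    fit_all_cross_models,
    fit_cross_model,
    models_from_frame,
    models_to_frame,
    predict_next,
)
from urbansami.io import INDICATORS, SamiTable
from urbansami.memory import fit_memory
from urbansami.synthetic import default_config, generate_panel

ZEROS = tuple(0.0 for _ in INDICATORS)


def _two_indicator_table(n=60, seed=0, rho_noise=0.1):
    rng = np.random.default_rng(seed)
    d = {ind: rng.normal(0, 0.3, n) for ind in ("a_ind", "b_ind")}
    d1 = {
        "a_ind": 0.5 * d["a_ind"] + 0.2 * d["b_ind"] + rng.normal(0, rho_noise, n),
        "b_ind": 0.7 * d["b_ind"] + rng.normal(0, rho_noise, n),
    }
    rows = []
    for year, vals in ((1991, d), (2000, d1)):
        for ind, v in vals.items():
            rows.append(pd.DataFrame({
                "city_id": [str(i) for i in range(n)],
                "indicator": ind, "year": year, "D": v,
            }))
    return SamiTable(pd.concat(rows, ignore_index=True))


class TestCrossModel:
    def test_noise_free_exact_recovery(self):
        cfg = default_config(seed=2, n_cities=200, noise_sd=ZEROS)
        _, truth, _ = generate_panel(cfg)
        C = np.asarray(cfg.dynamics_matrix)
        model = fit_cross_model(truth, "homicides", (1991, 2000))
        j = list(INDICATORS).index("homicides")
        for k, ind in enumerate(INDICATORS):
            assert model.coefficients[ind] == pytest.approx(C[j, k], abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)

    def test_r_squared_equals_independent_sse_ratio(self):
        table = _two_indicator_table(seed=5)
        model = fit_cross_model(table, "a_ind", (1991, 2000))
        wide = table.pivot(1991)[sorted(["a_ind", "b_ind"])]
        y = table.series("a_ind", 2000).loc[wide.index].to_numpy()
        pred = model.predict(wide)
        sse = np.sum((y - pred) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert model.r_squared == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_eight_predictor_r2_dominates_single_lag(self, truth_table):
        # adding predictors can never reduce in-sample explained variance
        for ind in ("homicides", "illiteracy"):
            model = fit_cross_model(truth_table, ind, (1991, 2000))
            mem = fit_memory(truth_table, ind, (1991, 2000))
            assert model.r_squared >= mem.rho**2 - 1e-12

    def test_robust_flag_keeps_coefficients(self, truth_table):
        plain = fit_cross_model(truth_table, "homicides", (1991, 2000))
        robust = fit_cross_model(truth_table, "homicides", (1991, 2000), robust=True)
        for ind in INDICATORS:
            assert robust.coefficients[ind] == pytest.approx(
                plain.coefficients[ind], abs=1e-12)
        assert robust.robust and not plain.robust

    def test_rank_deficiency_names_predictors(self):
        table = _two_indicator_table(seed=1)
        dup = table.frame[table.frame["indicator"] == "a_ind"].copy()
        dup["indicator"] = "c_ind"
        bad = SamiTable(pd.concat([table.frame, dup], ignore_index=True))
        with pytest.raises(DegenerateDataError, match="_ind"):
            fit_cross_model(bad, "a_ind", (1991, 2000))

    def test_too_few_cities_rejected(self):
        table = _two_indicator_table(n=5)
        with pytest.raises(DegenerateDataError, match="10"):
            fit_cross_model(table, "a_ind", (1991, 2000))

    def test_ridge_option_shrinks(self):
        table = _two_indicator_table(seed=8)
        plain = fit_cross_model(table, "a_ind", (1991, 2000))
        ridged = fit_cross_model(table, "a_ind", (1991, 2000), ridge=50.0)
        assert abs(ridged.coefficients["a_ind"]) < abs(plain.coefficients["a_ind"])


class TestCrossCorrelation:
    def test_identity_lag_diagonal_one(self):
        table = _two_indicator_table(seed=3)
        frame = table.frame.copy()
        lagged = frame[frame["year"] == 1991].copy()
        lagged["year"] = 2000
        ident = SamiTable(pd.concat([frame[frame["year"] == 1991], lagged],
                                    ignore_index=True))
        mat = cross_correlation_matrix(ident, (1991, 2000))
        np.testing.assert_allclose(np.diag(mat.to_numpy(dtype=float)), 1.0, atol=1e-12)

    def test_hand_computed_toy_pair(self):
        d0 = np.array([0.1, -0.2, 0.3, 0.0, -0.1])
        d1 = np.array([0.2, -0.1, 0.2, 0.1, -0.3])
        rows = []
        for year, vals in ((1991, {"a_ind": d0, "b_ind": d0[::-1]}),
                           (2000, {"a_ind": d1, "b_ind": d1[::-1]})):
            for ind, v in vals.items():
                rows.append(pd.DataFrame({
                    "city_id": list("vwxyz"), "indicator": ind,
                    "year": year, "D": v}))
        table = SamiTable(pd.concat(rows, ignore_index=True))
        mat = cross_correlation_matrix(table, (1991, 2000))
        expected = np.corrcoef(d1, d0)[0, 1]  # textbook Pearson by hand
        assert mat.loc["a_ind", "a_ind"] == pytest.approx(expected, abs=1e-12)

    def test_sparse_pair_is_nan(self):
        table = _two_indicator_table(n=2)
        mat = cross_correlation_matrix(table, (1991, 2000))
        assert mat.isna().all().all()

    def test_synthetic_diagonal_dominates_rows(self, truth_table):
        # with diagonal dynamics every indicator is most correlated with its
        # own past value
        mat = cross_correlation_matrix(truth_table, (1991, 2000)).to_numpy(dtype=float)
        for i in range(mat.shape[0]):
            assert np.nanargmax(np.abs(mat[i])) == i


class TestAveragingAndPrediction:
    def _model(self, c1, indicator="a_ind", intercept=0.0):
        return ForecastModel(
            indicator=indicator, year_pair=(1991, 2000), intercept=intercept,
            coefficients={"a_ind": c1, "b_ind": 0.0},
        )

    def test_average_idempotent(self):
        m = self._model(0.3)
        avg = average_models([m, m])
        assert avg.coefficients == m.coefficients
        assert avg.intercept == m.intercept
        assert avg.source_pairs == [(1991, 2000), (1991, 2000)]

    def test_average_arithmetic(self):
        avg = average_models([self._model(0.2), self._model(0.4)])
        assert avg.coefficients["a_ind"] == pytest.approx(0.3)

    def test_mismatched_predictors_rejected(self):
        other = ForecastModel(indicator="a_ind", year_pair=None, intercept=0.0,
                              coefficients={"a_ind": 0.1})
        with pytest.raises(ValueError, match="predictor"):
            average_models([self._model(0.2), other])

    def test_constant_model_prediction(self):
        table = _two_indicator_table(seed=2)
        models = {"a_ind": ForecastModel(
            indicator="a_ind", year_pair=None, intercept=0.1,
            coefficients={"a_ind": 0.0, "b_ind": 0.0})}
        predicted, n_skipped = predict_next(table, models, 2000, 2010)
        assert n_skipped == 0
        np.testing.assert_allclose(predicted.frame["D"], 0.1)

    def test_three_city_hand_computed(self):
        rows = []
        vals = {"a_ind": [0.1, -0.2, 0.0], "b_ind": [0.3, 0.1, -0.1]}
        for ind, v in vals.items():
            rows.append(pd.DataFrame({
                "city_id": list("pqr"), "indicator": ind, "year": 2010, "D": v}))
        table = SamiTable(pd.concat(rows, ignore_index=True))
        model = ForecastModel(indicator="a_ind", year_pair=None, intercept=0.05,
                              coefficients={"a_ind": 0.5, "b_ind": -0.2})
        predicted, _ = predict_next(table, {"a_ind": model}, 2010, 2020)
        got = predicted.series("a_ind", 2020)
        assert got["p"] == pytest.approx(0.05 + 0.5 * 0.1 - 0.2 * 0.3)
        assert got["q"] == pytest.approx(0.05 - 0.5 * 0.2 - 0.2 * 0.1)
        assert got["r"] == pytest.approx(0.05 + 0.2 * 0.1)

    def test_incomplete_predictor_rows_skipped(self):
        table = _two_indicator_table(seed=2)
        frame = table.frame
        drop = (frame["indicator"] == "b_ind") & (frame["city_id"] == "0") \
            & (frame["year"] == 2000)
        table = SamiTable(frame[~drop].reset_index(drop=True))
        models = {"a_ind": self._model(0.3)}
        _, n_skipped = predict_next(table, models, 2000, 2010)
        assert n_skipped == 1

    def test_off_step_horizon_warns(self):
        table = _two_indicator_table(seed=2)
        with pytest.warns(UserWarning, match="one-step"):
            predict_next(table, {"a_ind": self._model(0.3)}, 2000, 2030,
                         census_step=10)

    def test_prediction_linearity(self):
        model = self._model(0.4, intercept=0.07)
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a_ind", "b_ind"])
        Y = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a_ind", "b_ind"])
        a, b = 0.3, 1.7
        lhs = model.predict(a * X + b * Y)
        rhs = a * model.predict(X) + b * model.predict(Y) - (a + b - 1) * model.intercept
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_models_frame_round_trip(self, truth_table):
        models = fit_all_cross_models(truth_table)
        frame = models_to_frame(models)
        again = models_from_frame(frame)
        key = ("homicides", (1991, 2000))
        for ind in INDICATORS:
            assert again[key].coefficients[ind] == pytest.approx(
                models[key].coefficients[ind], rel=1e-9)


class TestComparison:
    def _tables(self, shift=0.0, n=80, seed=4):
        rng = np.random.default_rng(seed)
        emp = pd.DataFrame({
            "city_id": [str(i) for i in range(n)], "indicator": "a_ind",
            "year": 2010, "D": rng.normal(0, 0.3, n),
        })
        pred = emp.copy()
        pred["D"] = pred["D"] + shift
        return SamiTable(pred), SamiTable(emp)

    def test_identity_zero_distance(self):
        pred, emp = self._tables()
        rep = compare_predicted_empirical(pred, emp, n_boot=300, seed=0)
        assert rep.cdf_distance.loc[0, "max_cdf_distance"] == 0.0
        assert rep.mean_difference.loc[0, "mean_difference"] == 0.0

    def test_shift_detected_in_every_group(self):
        pred, emp = self._tables(shift=0.1)
        rep = compare_predicted_empirical(pred, emp, n_boot=300, seed=0)
        assert rep.mean_difference.loc[0, "mean_difference"] == pytest.approx(0.1)
        g = rep.group_means.pivot_table(index=["indicator", "group"],
                                        columns="source", values="mean")
        for _, row in g.iterrows():
            assert row["predicted"] - row["empirical"] == pytest.approx(0.1, abs=1e-12)

    def test_no_overlap_raises(self):
        pred, emp = self._tables()
        pred.frame["year"] = 2020
        with pytest.raises(ValueError, match="no .*keys|share no"):
            compare_predicted_empirical(pred, emp, n_boot=100, seed=0)

    def test_cdf_distance_shrinks_with_sample_size(self):
        # predictions from the true model: the distributional gap between
        # predicted and realized residuals shrinks as the system grows
        dists = {}
        for n in (200, 2000):
            cfg = default_config(seed=31, n_cities=n)
            _, truth, _ = generate_panel(cfg)
            models = {ind: fit_cross_model(truth, ind, (1991, 2000))
                      for ind in truth.indicators}
            pred, _ = predict_next(truth, models, 2000, 2010)
            rep = compare_predicted_empirical(pred, truth, n_boot=100, seed=0)
            dists[n] = rep.cdf_distance["max_cdf_distance"].mean()
        assert dists[2000] < dists[200]
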