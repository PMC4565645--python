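import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

from urbansami.allometry import (
    MajorAxisRegression,
    fit_allometry,
    fits_from_frame,
    fits_to_frame,
    major_axis_slope,
    per_capita_bias,
    per_capita_group_means,
)
from urbansami.exceptions import DegenerateDataError
from conftest import make_exact_panel


def brute_force_orthogonal_slope(x, y):
    """Independent oracle: minimize summed squared perpendicular distances.

    Parametrizes the line by its angle theta; for a fixed direction the
    optimal offset centers the residuals, so the objective reduces to a 1-d
    search over theta, done by dense grid plus bounded refinement.
    """
    u, v = x - x.mean(), y - y.mean()

    def cost(theta):
        return np.mean((u * np.sin(theta) - v * np.cos(theta)) ** 2)

    thetas = np.linspace(-np.pi / 2, np.pi / 2, 4001)
    best = thetas[np.argmin([cost(t) for t in thetas])]
    res = optimize.minimize_scalar(
        cost, bounds=(best - 2e-3, best + 2e-3), method="bounded",
        options={"xatol": 1e-13},
    )
    return np.tan(res.x)


def _random_instance(rng):
    n = int(rng.integers(5, 21))
    x = rng.uniform(-3, 3, n)
    slope = rng.uniform(-3, 3)
    y = rng.uniform(-1, 1) + slope * x + rng.normal(0, 0.5, n)
    return x, y


class TestMajorAxisSlope:
    def test_exact_line_recovered(self, exact_panel):
        fit = fit_allometry(exact_panel, "homicides", 2000, n_boot=100, seed=0)
        assert fit.intercept == pytest.approx(2.0, abs=1e-10)
        assert fit.exponent == pytest.approx(1.5, abs=1e-10)
        assert fit.rho == pytest.approx(1.0, abs=1e-12)
        assert fit.se_exponent == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(30):
            x, y = _random_instance(rng)
            est = MajorAxisRegression(se_method="analytic").fit(x, y)
            assert est.slope_ == pytest.approx(
                brute_force_orthogonal_slope(x, y), abs=1e-6)

    def test_matches_scipy_odr(self):
        # cross-check against the iterative orthogonal-distance implementation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DeprecationWarning)
            from scipy import odr
        rng = np.random.default_rng(7)
        x = rng.uniform(2, 7, 50)
        y = 1.0 + 1.35 * x + rng.normal(0, 0.4, 50)
        est = MajorAxisRegression(se_method="analytic").fit(x, y)
        data = odr.RealData(x, y)
        out = odr.ODR(data, odr.unilinear, beta0=[1.0, 0.0]).run()
        # the iterative solver stops at its own convergence tolerance
        assert est.slope_ == pytest.approx(out.beta[0], abs=1e-4)
        assert est.intercept_ == pytest.approx(out.beta[1], abs=1e-4)

    @given(st.integers(0, 2**31 - 1))
    def test_swap_symmetry(self, seed):
        # defining property of the major axis: exchanging the axes inverts
        # the slope
        rng = np.random.default_rng(seed)
        x, y = _random_instance(rng)
        _, _, sxx, syy, sxy = _moments(x, y)
        if abs(sxy) < 1e-8 or sxx < 1e-8 or syy < 1e-8:
            return
        b = major_axis_slope(sxx, syy, sxy)
        b_swapped = major_axis_slope(syy, sxx, sxy)
        assert b * b_swapped == pytest.approx(1.0, rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_positive_covariance_gives_positive_slope(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(-2, 2, 12))
        y = np.sort(rng.uniform(-2, 2, 12))
        _, _, sxx, syy, sxy = _moments(x, y)
        if sxy <= 0 or sxx == 0:
            return
        assert major_axis_slope(sxx, syy, sxy) > 0

    def test_rho_is_textbook_pearson(self):
        rng = np.random.default_rng(5)
        x, y = _random_instance(rng)
        est = MajorAxisRegression(se_method="analytic").fit(x, y)
        assert est.rho_ == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_variance_ratio_limits(self):
        # as the assumed y-error dominates, the fit approaches ordinary
        # least squares of y on x
        rng = np.random.default_rng(9)
        x, y = _random_instance(rng)
        b_ols = np.polyfit(x, y, 1)[0]
        est = MajorAxisRegression(variance_ratio=1e8, se_method="analytic").fit(x, y)
        assert est.slope_ == pytest.approx(b_ols, rel=1e-6)

    def test_sxy_zero_tie_break(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([0.0, 2.0, 0.0, 0.0, -2.0, 0.0])  # Sxy = 0, Syy > Sxx
        with pytest.warns(UserWarning, match="degenerate"):
            est = MajorAxisRegression(se_method="analytic").fit(x, y)
        assert est.slope_ > 0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateDataError):
            MajorAxisRegression().fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(DegenerateDataError, match="variance"):
            MajorAxisRegression().fit(np.ones(5), np.arange(5.0))

    def test_sklearn_params_round_trip(self):
        est = MajorAxisRegression(variance_ratio=2.0, n_boot=50)
        clone_params = est.get_params()
        assert clone_params["variance_ratio"] == 2.0
        est.set_params(n_boot=10)
        assert est.n_boot == 10


def _moments(x, y):
    from urbansami.allometry import _moments as m
    return m(np.asarray(x, float), np.asarray(y, float))


class TestStandardErrors:
    def test_analytic_agrees_with_bootstrap(self):
        rng = np.random.default_rng(21)
        x = rng.normal(4, 0.8, 600)
        y = -1.0 + 1.2 * x + rng.normal(0, 0.3, 600)
        boot = MajorAxisRegression(se_method="bootstrap", n_boot=2000,
                                   random_state=1).fit(x, y)
        ana = MajorAxisRegression(se_method="analytic").fit(x, y)
        assert ana.se_slope_ == pytest.approx(boot.se_slope_, rel=0.2)
        assert ana.se_intercept_ == pytest.approx(boot.se_intercept_, rel=0.2)

    def test_small_sample_bootstrap_warns(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.2, 2.8, 4.4])
        with pytest.warns(UserWarning, match="unreliable"):
            MajorAxisRegression(n_boot=50, random_state=0).fit(x, y)


class TestPerCapita:
    @pytest.mark.parametrize("beta,expected_bias,expected_label", [
        (1.0, 0.0, "linear"),
        (1.35, 0.35, "superlinear"),
        (0.33, -0.67, "sublinear"),
    ])
    def test_bias_classification(self, beta, expected_bias, expected_label):
        panel = make_exact_panel(exponent=beta)
        fit = fit_allometry(panel, "homicides", 2000, n_boot=50, seed=0)
        bias, label = per_capita_bias(fit, tolerance=1e-6)
        assert bias == pytest.approx(expected_bias, abs=1e-9)
        assert label == expected_label

    def test_per_capita_regression_recovers_beta_minus_one(self):
        # on exact data, fitting log10(Y/N) against log10 N gives beta - 1
        panel = make_exact_panel(exponent=1.35)
        frame = panel.frame.copy()
        frame["homicides"] = frame["homicides"] / frame["population"]
        from urbansami.io import CensusPanel
        pc_panel = CensusPanel(frame, ("homicides",))
        fit = fit_allometry(pc_panel, "homicides", 2000, n_boot=50, seed=0)
        assert fit.exponent == pytest.approx(0.35, abs=1e-9)

    def test_group_means_arithmetic(self, exact_panel):
        frame = exact_panel.frame.copy()
        frame["homicides"] = frame["population"] * np.array([0.2, 0.4, 0.2, 0.4])
        from urbansami.io import CensusPanel
        panel = CensusPanel(frame, ("homicides",))
        out = per_capita_group_means(panel, 2000, n_boot=2000, seed=0)
        assert out.loc[0, "mean_per_capita"] == pytest.approx(0.3)

    def test_constant_per_capita_zero_width_ci(self, exact_panel):
        frame = exact_panel.frame.copy()
        frame["homicides"] = frame["population"] * 0.25
        from urbansami.io import CensusPanel
        panel = CensusPanel(frame, ("homicides",))
        out = per_capita_group_means(panel, 2000, n_boot=2000, seed=0)
        assert out.loc[0, "ci_low"] == out.loc[0, "ci_high"] == pytest.approx(0.25)


class TestZeroHandlingAndSerialization:
    def test_zero_indicator_rows_dropped_and_counted(self):
        panel = make_exact_panel()
        frame = panel.frame.copy()
        frame.loc[0, "homicides"] = 0.0
        from urbansami.io import CensusPanel
        p = CensusPanel(frame, ("homicides",))
        fit = fit_allometry(p, "homicides", 2000, n_boot=50, seed=0)
        assert fit.n_used == 3
        assert fit.n_dropped_nonpositive == 1

    def test_offset_policy_keeps_zero_rows(self):
        panel = make_exact_panel()
        frame = panel.frame.copy()
        frame.loc[0, "homicides"] = 0.0
        from urbansami.io import CensusPanel
        p = CensusPanel(frame, ("homicides",))
        fit = fit_allometry(p, "homicides", 2000, n_boot=50, seed=0,
                            zero_policy="offset")
        assert fit.n_used == 4
        assert fit.n_dropped_nonpositive == 0

    def test_fit_frame_round_trip(self, exact_panel):
        fit = fit_allometry(exact_panel, "homicides", 2000, n_boot=50, seed=0)
        frame = fits_to_frame({("homicides", 2000): fit})
        again = fits_from_frame(frame)[("homicides", 2000)]
        assert again.exponent == pytest.approx(fit.exponent)
        assert again.intercept == pytest.approx(fit.intercept)
        assert again.n_used == fit.n_used
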