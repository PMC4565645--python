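"""Cross-indicator linear forecasting of the scale-adjusted metrics.

Each indicator's next-census residual is modeled as a linear combination of
all eight residuals at the current census,

    D_i(t + dt) = C0 + sum_k C_k D_k(t) + eta_i(t),

fitted by OLS per indicator and census interval.  For forecasting one census
ahead, the coefficients are assumed time-constant and averaged over the
available intervals; the prediction for each city is the plain linear
combination of its current residual vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import bootstrap_mean_ci, check_rng
from .exceptions import DegenerateDataError
from .io import SamiTable

__all__ = [
    "CrossIndicatorForecast",
    "ForecastModel",
    "fit_cross_model",
    "fit_all_cross_models",
    "cross_correlation_matrix",
    "average_models",
    "predict_next",
    "compare_predicted_empirical",
    "models_to_frame",
]


class CrossIndicatorForecast(BaseEstimator, RegressorMixin):
    """Multivariate OLS forecaster in the scikit-learn idiom.

    Parameters
    ----------
    robust : bool, default False
        Heteroskedasticity-consistent (HC1) coefficient SEs.
    ridge : float, default 0.0
        Optional L2 penalty for ill-conditioned designs (non-default; plain
        OLS is the reference method).

    Attributes after ``fit``: ``intercept_``, ``coef_`` (one per predictor),
    ``se_intercept_``, ``se_coef_``, ``r_squared_``, ``resid_sd_``,
    ``n_used_``.
    """

    def __init__(self, robust: bool = False, ridge: float = 0.0):
        self.robust = robust
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (cities x predictors)")
        n, k = X.shape
        if n < k + 2:
            raise DegenerateDataError(f"need at least {k + 2} complete cities, got {n}")
        design = sm.add_constant(X, has_constant="add")
        if self.ridge > 0.0:
            gram = design.T @ design + self.ridge * np.eye(k + 1)
            params = np.linalg.solve(gram, design.T @ y)
            fitted = design @ params
            resid = y - fitted
            sst = np.sum((y - y.mean()) ** 2)
            self.intercept_ = float(params[0])
            self.coef_ = params[1:].copy()
            self.se_intercept_ = float("nan")
            self.se_coef_ = np.full(k, np.nan)
            self.r_squared_ = float(1.0 - np.sum(resid**2) / sst)
            self.resid_sd_ = float(np.std(resid, ddof=k + 1))
        else:
            rank = np.linalg.matrix_rank(design)
            if rank < k + 1:
                _, sv, vt = np.linalg.svd(design - design.mean(0), full_matrices=False)
                null = np.abs(vt[-1])
                guilty = [f"x{j}" for j in np.argsort(null)[::-1][:2]]
                raise DegenerateDataError(
                    f"rank-deficient design (rank {rank} < {k + 1}); "
                    f"near-collinear predictors: {', '.join(guilty)}"
                )
            res = sm.OLS(y, design).fit(cov_type="HC1" if self.robust else "nonrobust")
            self.intercept_ = float(res.params[0])
            self.coef_ = np.asarray(res.params[1:], dtype=float)
            self.se_intercept_ = float(res.bse[0])
            self.se_coef_ = np.asarray(res.bse[1:], dtype=float)
            self.r_squared_ = float(res.rsquared)
            self.resid_sd_ = float(np.sqrt(res.mse_resid))
            self._result = res
        self.n_used_ = int(n)
        self.n_features_in_ = k
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


@dataclass
class ForecastModel:
    """Fitted (or averaged) cross-indicator linear model for one target."""

    indicator: str
    year_pair: tuple[int, int] | None
    intercept: float
    coefficients: dict[str, float]
    se_intercept: float = float("nan")
    coefficient_ses: dict[str, float] = field(default_factory=dict)
    r_squared: float = float("nan")
    resid_sd: float = float("nan")
    n_used: int = 0
    robust: bool = False
    source_pairs: list = field(default_factory=list)

    def predict(self, d_frame: pd.DataFrame) -> pd.Series:
        """Predicted target residual for a cities-x-indicators D matrix."""
        predictors = list(self.coefficients)
        missing = [p for p in predictors if p not in d_frame.columns]
        if missing:
            raise KeyError(f"predictor columns missing: {', '.join(missing)}")
        coef = np.array([self.coefficients[p] for p in predictors])
        return self.intercept + d_frame[predictors].to_numpy() @ coef


def _design_for_pair(table: SamiTable, indicator: str, year_pair):
    t0, t1 = year_pair
    wide0 = table.pivot(t0)
    target = table.series(indicator, t1)
    predictors = sorted(wide0.columns)
    joined = wide0[predictors].join(target.rename("_target"), how="inner").dropna()
    return joined[predictors], joined["_target"], predictors


def fit_cross_model(
    table: SamiTable,
    indicator: str,
    year_pair: tuple[int, int],
    robust: bool = False,
    ridge: float = 0.0,
) -> ForecastModel:
    """OLS fit of D_i(t+dt) on all indicators' D(t) for one interval.

    Uses the cities with a complete predictor vector at ``t`` and a target
    value at ``t+dt`` (at least 10).  Predictors are ordered alphabetically.
    """
    X, y, predictors = _design_for_pair(table, indicator, year_pair)
    if len(X) < 10:
        raise DegenerateDataError(
            f"need >= 10 complete cities for the cross model, got {len(X)}"
        )
    est = CrossIndicatorForecast(robust=robust, ridge=ridge)
    try:
        est.fit(X.to_numpy(), y.to_numpy())
    except DegenerateDataError as err:
        # translate positional predictor names into indicator names
        msg = str(err)
        for j, p in enumerate(predictors):
            msg = msg.replace(f"x{j}", p)
        raise DegenerateDataError(msg) from None
    return ForecastModel(
        indicator=indicator,
        year_pair=tuple(year_pair),
        intercept=est.intercept_,
        coefficients=dict(zip(predictors, est.coef_)),
        se_intercept=est.se_intercept_,
        coefficient_ses=dict(zip(predictors, est.se_coef_)),
        r_squared=est.r_squared_,
        resid_sd=est.resid_sd_,
        n_used=est.n_used_,
        robust=robust,
        source_pairs=[tuple(year_pair)],
    )


def fit_all_cross_models(table: SamiTable, robust: bool = False) -> dict:
    """Cross models for every indicator and consecutive census pair."""
    years = table.years
    models = {}
    for indicator in table.indicators:
        for t0, t1 in zip(years[:-1], years[1:]):
            models[(indicator, (t0, t1))] = fit_cross_model(
                table, indicator, (t0, t1), robust=robust
            )
    return models


def cross_correlation_matrix(table: SamiTable, year_pair: tuple[int, int]) -> pd.DataFrame:
    """Pearson correlations of D_i(t+dt) (rows) against D_j(t) (columns).

    Pairs with fewer than 3 common cities are reported as NaN.
    """
    t0, t1 = year_pair
    wide0, wide1 = table.pivot(t0), table.pivot(t1)
    indicators = sorted(set(wide0.columns) & set(wide1.columns))
    out = pd.DataFrame(index=indicators, columns=indicators, dtype=float)
    for i in indicators:       # row: target at t+dt
        for j in indicators:   # column: predictor at t
            joined = pd.concat([wide1[i], wide0[j]], axis=1, join="inner").dropna()
            if len(joined) < 3:
                out.loc[i, j] = np.nan
                continue
            out.loc[i, j] = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
    return out


def average_models(models: list[ForecastModel]) -> ForecastModel:
    """Unweighted arithmetic mean of coefficients across census intervals.

    All models must target the same indicator with identical predictor sets;
    the contributing intervals are recorded in ``source_pairs``.
    """
    if not models:
        raise ValueError("need at least one model to average")
    indicator = models[0].indicator
    predictors = sorted(models[0].coefficients)
    for m in models:
        if m.indicator != indicator:
            raise ValueError("cannot average models for different indicators")
        if sorted(m.coefficients) != predictors:
            raise ValueError("mismatched predictor sets across models")
    coeffs = {p: float(np.mean([m.coefficients[p] for m in models])) for p in predictors}
    return ForecastModel(
        indicator=indicator,
        year_pair=None,
        intercept=float(np.mean([m.intercept for m in models])),
        coefficients=coeffs,
        source_pairs=[m.year_pair for m in models],
    )


def predict_next(
    table: SamiTable,
    models: dict[str, ForecastModel],
    from_year: int,
    horizon_year: int,
    census_step: int | None = None,
) -> tuple[SamiTable, int]:
    """One-step-ahead forecast of every indicator's D at the horizon year.

    Applies each indicator's (averaged) model to the complete predictor rows
    at ``from_year``; cities with any missing predictor are skipped and
    counted.  Returns ``(predicted table, n_skipped_cities)``.  The model is
    one-step: a horizon further than one census interval away triggers a
    warning, not an error.
    """
    wide = table.pivot(from_year)
    if census_step is not None and horizon_year - from_year != census_step:
        warnings.warn(
            f"horizon {horizon_year} is not one census step ({census_step} years) "
            f"after {from_year}; the linear model is one-step-ahead"
        )
    complete = wide.dropna()
    n_skipped = len(wide) - len(complete)
    rows = []
    for indicator, model in models.items():
        pred = model.predict(complete)
        rows.append(pd.DataFrame({
            "city_id": complete.index,
            "indicator": indicator,
            "year": horizon_year,
            "D": np.asarray(pred, dtype=float),
        }))
    return SamiTable(pd.concat(rows, ignore_index=True)), n_skipped


@dataclass
class ComparisonReport:
    """Predicted-vs-empirical comparison for overlapping city-indicator keys."""

    group_means: pd.DataFrame   # indicator, group, source, mean, ci_low, ci_high, n
    cdf_distance: pd.DataFrame  # indicator, max vertical CDF distance, n
    mean_difference: pd.DataFrame  # indicator, mean(pred - emp)


def compare_predicted_empirical(
    predicted: SamiTable,
    empirical: SamiTable,
    n_boot: int = 10_000,
    seed=None,
) -> ComparisonReport:
    """Compare a predicted SAMI table against the empirical one.

    Matches on (city_id, indicator, year).  Per indicator it reports the
    predicted and empirical group means (using the empirical sign as the
    above/below grouping) with percentile-bootstrap CIs, the mean prediction
    error, and the maximum vertical distance between the two cumulative
    distributions (the two-sample Kolmogorov-Smirnov statistic).
    """
    keys = ["city_id", "indicator", "year"]
    merged = predicted.frame.merge(
        empirical.frame[keys + ["D"]], on=keys, suffixes=("_pred", "_emp")
    )
    if merged.empty:
        raise ValueError("predicted and empirical tables share no (city, indicator, year) keys")
    rng = check_rng(seed)
    mean_rows, cdf_rows, diff_rows = [], [], []
    for indicator, sub in merged.groupby("indicator"):
        pred = sub["D_pred"].to_numpy()
        emp = sub["D_emp"].to_numpy()
        cdf_rows.append({
            "indicator": indicator,
            "max_cdf_distance": float(stats.ks_2samp(pred, emp).statistic),
            "n": len(sub),
        })
        diff_rows.append({"indicator": indicator,
                          "mean_difference": float(np.mean(pred - emp))})
        group_mask = {"above": emp > 0, "below": emp <= 0}
        for group, mask in group_mask.items():
            if mask.sum() == 0:
                continue
            for source, vals in (("empirical", emp[mask]), ("predicted", pred[mask])):
                mean, lo, hi = bootstrap_mean_ci(vals, n_boot=n_boot, rng=rng)
                mean_rows.append({
                    "indicator": indicator, "group": group, "source": source,
                    "mean": mean, "ci_low": lo, "ci_high": hi, "n": int(mask.sum()),
                })
    return ComparisonReport(
        group_means=pd.DataFrame(mean_rows),
        cdf_distance=pd.DataFrame(cdf_rows),
        mean_difference=pd.DataFrame(diff_rows),
    )


def models_to_frame(models: dict) -> pd.DataFrame:
    """Serialize cross models: indicator, interval, C0..C8, SEs, R^2."""
    rows = []
    for m in models.values():
        row = {
            "indicator": m.indicator,
            "year_from": m.year_pair[0] if m.year_pair else None,
            "year_to": m.year_pair[1] if m.year_pair else None,
            "intercept": m.intercept,
            "se_intercept": m.se_intercept,
            "r_squared": m.r_squared,
            "resid_sd": m.resid_sd,
            "n_used": m.n_used,
            "robust": m.robust,
        }
        for p in sorted(m.coefficients):
            row[f"c_{p}"] = m.coefficients[p]
            row[f"se_{p}"] = m.coefficient_ses.get(p, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["indicator", "year_from"]).reset_index(drop=True)


def models_from_frame(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`models_to_frame`, keyed by indicator (and interval).

    Rows without an interval (averaged models) are keyed by indicator alone.
    """
    models = {}
    for _, r in frame.iterrows():
        predictors = sorted(c[2:] for c in frame.columns if c.startswith("c_"))
        pair = None
        if pd.notna(r.get("year_from")):
            pair = (int(r["year_from"]), int(r["year_to"]))
        m = ForecastModel(
            indicator=r["indicator"], year_pair=pair,
            intercept=float(r["intercept"]),
            coefficients={p: float(r[f"c_{p}"]) for p in predictors},
            coefficient_ses={p: float(r[f"se_{p}"]) for p in predictors
                             if f"se_{p}" in frame.columns},
            se_intercept=float(r.get("se_intercept", float("nan"))),
            r_squared=float(r.get("r_squared", float("nan"))),
            n_used=int(r["n_used"]) if pd.notna(r.get("n_used")) else 0,
        )
        models[(r["indicator"], pair) if pair else r["indicator"]] = m
    return models
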