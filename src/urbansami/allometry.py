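"""Power-law allometry between urban indicators and population size.

An indicator ``Y`` is modeled as ``Y = 10^A * N^beta``: a straight line in
log10-log10 space.  Because both axes carry comparable uncertainty, the line
is fitted by orthogonal-distance (major-axis) regression: the slope minimizes
the summed squared perpendicular distances of the points to the line, and the
line passes through the centroid.  With second moments ``Sxx, Syy, Sxy`` of
``(log10 N, log10 Y)`` the closed-form slope is

    b = [Syy - Sxx + sqrt((Syy - Sxx)^2 + 4 Sxy^2)] / (2 Sxy)

(the larger root of the eigenvalue problem of the covariance matrix).  A
variance-ratio knob ``lambda`` generalizes this to unequal error variances;
``lambda = 1`` is the equal-weight default matching unweighted orthogonal
distance regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import bootstrap_mean_ci, check_rng
from .exceptions import DegenerateDataError
from .io import CensusPanel

__all__ = [
    "MajorAxisRegression",
    "AllometricFit",
    "major_axis_slope",
    "fit_allometry",
    "fit_all_allometries",
    "per_capita_bias",
    "per_capita_group_means",
    "fits_to_frame",
]


def _moments(x: np.ndarray, y: np.ndarray):
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    return xm, ym, (u * u).mean(), (v * v).mean(), (u * v).mean()


def major_axis_slope(sxx, syy, sxy, variance_ratio: float = 1.0):
    """Closed-form generalized major-axis slope from second moments.

    Vectorized over leading dimensions.  ``variance_ratio`` is the assumed
    ratio of the error variance on y to that on x; 1 gives the major axis.
    For ``sxy == 0`` the slope direction is degenerate; the convention is to
    return ``sign(syy - lambda*sxx) * sqrt(syy/sxx)``.
    """
    lam = variance_ratio
    sxx, syy, sxy = np.asarray(sxx, float), np.asarray(syy, float), np.asarray(sxy, float)
    d = syy - lam * sxx
    root = np.sqrt(d * d + 4.0 * lam * sxy * sxy)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (d + root) / (2.0 * sxy)
    tie = sxy == 0
    if np.any(tie):
        fallback = np.sign(d) * np.sqrt(np.divide(syy, sxx, out=np.ones_like(d), where=sxx > 0))
        slope = np.where(tie, fallback, slope)
    return slope if slope.ndim else float(slope)


def _slope_gradient(sxx, syy, sxy, lam):
    """Gradient of the closed-form slope w.r.t. (Sxx, Syy, Sxy)."""
    d = syy - lam * sxx
    root = np.sqrt(d * d + 4.0 * lam * sxy * sxy)
    g_syy = (1.0 + d / root) / (2.0 * sxy)
    g_sxx = -lam * g_syy
    g_sxy = 2.0 * lam / root - (d + root) / (2.0 * sxy * sxy)
    return g_sxx, g_syy, g_sxy


class MajorAxisRegression(BaseEstimator, RegressorMixin):
    """Major-axis (orthogonal-distance) line fit in the scikit-learn idiom.

    Parameters
    ----------
    variance_ratio : float, default 1.0
        Assumed y-to-x error-variance ratio; 1 weights both axes equally.
    se_method : {"bootstrap", "analytic"}, default "bootstrap"
        Standard errors by seeded nonparametric bootstrap (resampling
        observations and refitting) or by the large-n delta method applied to
        the closed-form slope as a function of the sample moments.
    n_boot : int, default 1000
        Bootstrap resamples when ``se_method="bootstrap"``.
    random_state : int or Generator, optional
        Seeds the bootstrap.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted line ``y = intercept_ + slope_ * x``.
    se_slope_, se_intercept_ : float
    rho_ : float
        Plain Pearson correlation of the (x, y) pairs.
    n_used_ : int
    """

    def __init__(self, variance_ratio: float = 1.0, se_method: str = "bootstrap",
                 n_boot: int = 1000, random_state=None):
        self.variance_ratio = variance_ratio
        self.se_method = se_method
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("MajorAxisRegression is a single-feature line fit")
            x = X[:, 0]
        else:
            x = X
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("inputs must be finite")
        n = x.size
        if n < 3:
            raise DegenerateDataError("need at least 3 points for a line fit")
        xm, ym, sxx, syy, sxy = _moments(x, y)
        if sxx == 0.0:
            raise DegenerateDataError("zero variance in x: vertical collinear points")
        if sxy == 0.0:
            warnings.warn("S_xy = 0: major-axis direction is degenerate; "
                          "using the sign of (Syy - lambda*Sxx) tie-break")
        self.slope_ = float(major_axis_slope(sxx, syy, sxy, self.variance_ratio))
        self.intercept_ = float(ym - self.slope_ * xm)
        denom = np.sqrt(sxx * syy)
        self.rho_ = float(sxy / denom) if denom > 0 else 0.0
        self.n_used_ = int(n)
        self.n_features_in_ = 1
        if self.se_method == "bootstrap":
            self.se_slope_, self.se_intercept_ = self._bootstrap_se(x, y)
        elif self.se_method == "analytic":
            self.se_slope_, self.se_intercept_ = self._analytic_se(x, y)
        else:
            raise ValueError(f"unknown se_method {self.se_method!r}")
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        return self.intercept_ + self.slope_ * x

    # -- uncertainty ----------------------------------------------------

    def _bootstrap_se(self, x, y):
        n = x.size
        if n < 10:
            warnings.warn(f"bootstrap SE on only {n} points is unreliable")
        rng = check_rng(self.random_state)
        idx = rng.integers(0, n, size=(self.n_boot, n))
        xb, yb = x[idx], y[idx]
        xbm = xb.mean(axis=1, keepdims=True)
        ybm = yb.mean(axis=1, keepdims=True)
        u, v = xb - xbm, yb - ybm
        sxx = (u * u).mean(axis=1)
        syy = (v * v).mean(axis=1)
        sxy = (u * v).mean(axis=1)
        ok = sxx > 0
        slopes = major_axis_slope(sxx[ok], syy[ok], sxy[ok], self.variance_ratio)
        intercepts = ybm[ok, 0] - slopes * xbm[ok, 0]
        return float(np.std(slopes, ddof=1)), float(np.std(intercepts, ddof=1))

    def _analytic_se(self, x, y):
        n = x.size
        xm, ym, sxx, syy, sxy = _moments(x, y)
        if sxy == 0.0:
            return float("nan"), float("nan")
        u, v = x - xm, y - ym
        g_sxx, g_syy, g_sxy = _slope_gradient(sxx, syy, sxy, self.variance_ratio)
        # influence values of the slope and intercept per observation
        inf_b = (g_sxx * (u * u - sxx) + g_syy * (v * v - syy) + g_sxy * (u * v - sxy))
        inf_a = v - xm * inf_b - self.slope_ * u
        return (float(np.std(inf_b, ddof=1) / np.sqrt(n)),
                float(np.std(inf_a, ddof=1) / np.sqrt(n)))


@dataclass
class AllometricFit:
    """Result of one indicator-year allometric fit."""

    indicator: str
    year: int
    intercept: float      # A: log10 of the indicator at N = 1
    exponent: float       # beta: allometric scaling exponent
    se_intercept: float
    se_exponent: float
    rho: float            # Pearson correlation of (log10 N, log10 Y)
    n_used: int
    n_dropped_nonpositive: int
    se_method: str = "bootstrap"
    notes: list = field(default_factory=list)


def _prepare_log_pairs(panel: CensusPanel, indicator: str, year: int,
                       zero_policy: str = "drop", offset: float = 1.0):
    sub = panel.subset(year)
    y_raw = sub[indicator].to_numpy(dtype=float)
    n_raw = sub["population"].to_numpy(dtype=float)
    city = sub["city_id"].to_numpy()
    valid = np.isfinite(y_raw) & np.isfinite(n_raw) & (n_raw > 0)
    if zero_policy == "offset":
        y_adj = y_raw + offset
        keep = valid & (y_adj > 0)
        y_use = y_adj
    elif zero_policy == "drop":
        keep = valid & (y_raw > 0)
        y_use = y_raw
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    n_dropped = int(valid.sum() - keep.sum())
    return (np.log10(n_raw[keep]), np.log10(y_use[keep]), city[keep], n_dropped)


def fit_allometry(
    panel: CensusPanel,
    indicator: str,
    year: int,
    variance_ratio: float = 1.0,
    se_method: str = "bootstrap",
    n_boot: int = 1000,
    seed=None,
    zero_policy: str = "drop",
) -> AllometricFit:
    """Fit ``log10 Y = A + beta log10 N`` by major-axis regression.

    Rows with nonpositive indicator values are excluded and counted
    (``zero_policy="drop"``); ``zero_policy="offset"`` instead adds 1 to the
    indicator before taking logs.
    """
    x, y, _, n_dropped = _prepare_log_pairs(panel, indicator, year, zero_policy)
    est = MajorAxisRegression(variance_ratio=variance_ratio, se_method=se_method,
                              n_boot=n_boot, random_state=seed).fit(x, y)
    return AllometricFit(
        indicator=indicator,
        year=year,
        intercept=est.intercept_,
        exponent=est.slope_,
        se_intercept=est.se_intercept_,
        se_exponent=est.se_slope_,
        rho=est.rho_,
        n_used=est.n_used_,
        n_dropped_nonpositive=n_dropped,
        se_method=se_method,
    )


def fit_all_allometries(panel: CensusPanel, seed=None, **kwargs) -> dict:
    """Fit every indicator-year combination; returns {(indicator, year): fit}.

    The seed is split deterministically across fits so results do not depend
    on iteration order side effects.
    """
    rng = check_rng(seed)
    fits = {}
    for indicator in panel.indicators:
        for year in panel.years:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            fits[(indicator, year)] = fit_allometry(
                panel, indicator, year, seed=sub_seed, **kwargs
            )
    return fits


def per_capita_bias(fit: AllometricFit, tolerance: float = 1e-9):
    """Exponent of the residual population factor in the per-capita value.

    Per-capita values scale as ``Y/N ~ N^(beta - 1)``; the bias exponent
    ``beta - 1`` classifies the allometry as superlinear (> 0, biased toward
    large cities), sublinear (< 0, biased toward small cities), or linear.
    """
    bias = fit.exponent - 1.0
    if abs(bias) <= tolerance:
        label = "linear"
    elif bias > 0:
        label = "superlinear"
    else:
        label = "sublinear"
    return bias, label


def per_capita_group_means(
    panel: CensusPanel, year: int, n_boot: int = 10_000, seed=None
) -> pd.DataFrame:
    """Unweighted mean per-capita indicator values with 95% bootstrap CIs."""
    sub = panel.subset(year)
    rng = check_rng(seed)
    rows = []
    for indicator in panel.indicators:
        vals = (sub[indicator] / sub["population"]).dropna().to_numpy()
        mean, lo, hi = bootstrap_mean_ci(vals, n_boot=n_boot, rng=rng)
        rows.append({"indicator": indicator, "year": year, "mean_per_capita": mean,
                     "ci_low": lo, "ci_high": hi, "n_cities": vals.size})
    return pd.DataFrame(rows)


def fits_to_frame(fits: dict) -> pd.DataFrame:
    """Serialize fits to a table with one row per indicator-year."""
    rows = [
        {
            "indicator": f.indicator, "year": f.year,
            "intercept": f.intercept, "se_intercept": f.se_intercept,
            "exponent": f.exponent, "se_exponent": f.se_exponent,
            "rho": f.rho, "n_used": f.n_used,
            "n_dropped_nonpositive": f.n_dropped_nonpositive,
            "se_method": f.se_method,
        }
        for f in fits.values()
    ]
    return pd.DataFrame(rows).sort_values(["indicator", "year"]).reset_index(drop=True)


def fits_from_frame(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`fits_to_frame`; returns {(indicator, year): fit}."""
    fits = {}
    for r in frame.itertuples():
        fits[(r.indicator, int(r.year))] = AllometricFit(
            indicator=r.indicator, year=int(r.year),
            intercept=float(r.intercept), exponent=float(r.exponent),
            se_intercept=float(r.se_intercept), se_exponent=float(r.se_exponent),
            rho=float(r.rho), n_used=int(r.n_used),
            n_dropped_nonpositive=int(r.n_dropped_nonpositive),
            se_method=str(r.se_method),
        )
    return fits
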