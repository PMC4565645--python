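"""One-lag memory of the scale-adjusted metrics and its continuous limit.

Across consecutive censuses the residuals obey, to good approximation, the
linear map ``D(t + dt) = A + alpha D(t)`` fitted by ordinary least squares.
Taking dt small turns the map into ``dD/dt = A + (alpha - 1) D``, whose
solution relaxes exponentially toward ``A / (1 - alpha)`` when ``alpha < 1``
with characteristic time ``1 / (1 - alpha)``; ``alpha = 1`` gives linear
drift and ``alpha > 1`` exponential departure from the law.

Diagnostics mirror the residual checks of the analysis: normalized residuals
are compared to a standard Gaussian with the Cramér-von Mises statistic, and
heteroskedasticity is probed by the residual SD in five equal-width windows
of D(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import check_rng
from .exceptions import DegenerateDataError
from .io import SamiTable

__all__ = [
    "LagMemoryRegression",
    "MemoryFit",
    "fit_memory",
    "fit_all_memory",
    "OdeSolution",
    "ode_solution",
    "characteristic_time",
    "DiagnosticsResult",
    "residual_diagnostics",
    "cvm_normal_test",
    "memory_fits_to_frame",
]

_ALPHA_ONE_TOL = 1e-12  # |1 - alpha| below this selects the linear branch


class LagMemoryRegression(BaseEstimator, RegressorMixin):
    """OLS of a metric on its own one-census-lagged value (scikit-learn idiom).

    Attributes after fit: ``intercept_``, ``slope_``, ``se_intercept_``,
    ``se_slope_``, ``rho_`` (Pearson correlation of the pairs), ``n_used_``.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        y = np.asarray(y, dtype=float)
        if x.size < 3:
            raise DegenerateDataError("need at least 3 cities present at both censuses")
        if np.var(x) == 0:
            raise DegenerateDataError("zero variance in the lagged metric")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.se_intercept_ = float(res.bse[0])
        self.se_slope_ = float(res.bse[1])
        self.rho_ = float(np.corrcoef(x, y)[0, 1])
        self.n_used_ = int(x.size)
        self.n_features_in_ = 1
        self._result = res
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        return self.intercept_ + self.slope_ * x


@dataclass
class MemoryFit:
    indicator: str
    year_pair: tuple[int, int]
    intercept: float
    slope: float
    se_slope: float
    se_intercept: float
    rho: float
    n_used: int


def _paired_series(table: SamiTable, indicator: str, year_pair: tuple[int, int]):
    t0, t1 = year_pair
    d0 = table.series(indicator, t0)
    d1 = table.series(indicator, t1)
    common = d0.index.intersection(d1.index)
    return d0.loc[common].to_numpy(), d1.loc[common].to_numpy(), common


def fit_memory(table: SamiTable, indicator: str, year_pair: tuple[int, int]) -> MemoryFit:
    """OLS fit of D(t+dt) on D(t) for one indicator and census pair."""
    x, y, _ = _paired_series(table, indicator, year_pair)
    est = LagMemoryRegression().fit(x, y)
    return MemoryFit(
        indicator=indicator, year_pair=tuple(year_pair),
        intercept=est.intercept_, slope=est.slope_,
        se_slope=est.se_slope_, se_intercept=est.se_intercept_,
        rho=est.rho_, n_used=est.n_used_,
    )


def fit_all_memory(table: SamiTable) -> dict:
    """Memory fits for every indicator and consecutive census pair."""
    years = table.years
    fits = {}
    for indicator in table.indicators:
        for t0, t1 in zip(years[:-1], years[1:]):
            fits[(indicator, (t0, t1))] = fit_memory(table, indicator, (t0, t1))
    return fits


@dataclass
class OdeSolution:
    """Continuous-time trajectory of the one-lag map.

    ``evaluate(t)`` returns ``A/(1-alpha) + [k - A/(1-alpha)] exp(-(1-alpha)t)``
    for ``alpha != 1`` and ``A t + k`` on the linear branch, with ``k`` the
    initial condition D(0).
    """

    A: float
    alpha: float
    k: float
    asymptote: float = field(init=False)
    characteristic_time: float = field(init=False)

    def __post_init__(self):
        if abs(1.0 - self.alpha) < _ALPHA_ONE_TOL:
            self.asymptote = math.nan
        else:
            self.asymptote = self.A / (1.0 - self.alpha)
        self.characteristic_time = characteristic_time(self.alpha)

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        if abs(1.0 - self.alpha) < _ALPHA_ONE_TOL:
            out = self.A * t + self.k
        else:
            out = self.asymptote + (self.k - self.asymptote) * np.exp(-(1.0 - self.alpha) * t)
        return out if out.ndim else float(out)

    __call__ = evaluate


def ode_solution(A: float, alpha: float, k: float) -> OdeSolution:
    """Closed-form solution of ``dD/dt = A + (alpha - 1) D`` with D(0) = k."""
    return OdeSolution(float(A), float(alpha), float(k))


def characteristic_time(alpha: float) -> float:
    """Relaxation e-folding time ``1/(1 - alpha)`` of the memory dynamics.

    Finite and positive for ``alpha < 1`` (smaller alpha, faster change);
    returns ``inf`` for ``alpha >= 1``, where there is no finite relaxation
    toward the law (never raises).
    """
    if alpha >= 1.0:
        return math.inf
    return 1.0 / (1.0 - alpha)


def cvm_normal_test(x, standardize: bool = True, composite: bool = False,
                    n_param_boot: int = 199, seed=None):
    """Cramér-von Mises test of normality; returns (statistic, p-value).

    Default: compare against the standard normal, optionally after
    standardizing the sample to mean 0 / SD 1 (the fixed-parameter variant
    used for the residual diagnostics).  ``composite=True`` calibrates the
    p-value for the estimated location/scale by a seeded parametric bootstrap
    instead of the fixed-parameter asymptotic distribution.
    """
    x = np.asarray(x, dtype=float)
    if standardize:
        x = (x - x.mean()) / x.std()
    res = stats.cramervonmises(x, "norm")
    if not composite:
        return float(res.statistic), float(res.pvalue)
    rng = check_rng(seed)
    stat = res.statistic
    boot = np.empty(n_param_boot)
    for b in range(n_param_boot):
        sim = rng.standard_normal(x.size)
        sim = (sim - sim.mean()) / sim.std()
        boot[b] = stats.cramervonmises(sim, "norm").statistic
    p = (1.0 + np.sum(boot >= stat)) / (n_param_boot + 1.0)
    return float(stat), float(p)


@dataclass
class DiagnosticsResult:
    """Residual diagnostics of one memory fit."""

    indicator: str
    year_pair: tuple[int, int]
    xi: np.ndarray            # normalized residuals: mean 0, SD 1
    cvm_statistic: float
    cvm_p: float
    window_centers: np.ndarray  # mean D(t) per window
    window_sd: np.ndarray       # SD of D(t+dt) per window (NaN if < 2 points)
    window_counts: np.ndarray


def residual_diagnostics(
    fit: MemoryFit, table: SamiTable, n_windows: int = 5, composite: bool = False,
    seed=None,
) -> DiagnosticsResult:
    """Normality and heteroskedasticity diagnostics for a memory fit.

    Residuals are standardized to mean 0 / SD 1 and tested against the
    standard normal with the Cramér-von Mises statistic.  The windowed SD of
    D(t+dt) is computed over ``n_windows`` equal-width, right-closed bins of
    D(t); windows with fewer than 2 points report NaN.
    """
    x, y, _ = _paired_series(table, fit.indicator, fit.year_pair)
    resid = y - (fit.intercept + fit.slope * x)
    xi = (resid - resid.mean()) / resid.std()
    stat, p = cvm_normal_test(xi, standardize=False, composite=composite, seed=seed)

    edges = np.linspace(x.min(), x.max(), n_windows + 1)
    # right-closed bins; the lowest edge is included in the first window
    which = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, n_windows - 1)
    centers = np.full(n_windows, np.nan)
    sds = np.full(n_windows, np.nan)
    counts = np.zeros(n_windows, dtype=int)
    for w in range(n_windows):
        mask = which == w
        counts[w] = mask.sum()
        if counts[w] >= 1:
            centers[w] = x[mask].mean()
        if counts[w] >= 2:
            sds[w] = y[mask].std(ddof=1)
    return DiagnosticsResult(fit.indicator, fit.year_pair, xi, stat, p,
                             centers, sds, counts)


def memory_fits_to_frame(fits: dict) -> pd.DataFrame:
    """Serialize memory fits, one row per indicator and census pair."""
    rows = [
        {
            "indicator": f.indicator,
            "year_from": f.year_pair[0], "year_to": f.year_pair[1],
            "intercept": f.intercept, "slope": f.slope,
            "se_slope": f.se_slope, "se_intercept": f.se_intercept,
            "rho": f.rho, "n_used": f.n_used,
        }
        for f in fits.values()
    ]
    return (pd.DataFrame(rows)
            .sort_values(["indicator", "year_from"])
            .reset_index(drop=True))
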