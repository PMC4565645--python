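"""Scale-adjusted metrics: allometric residuals, baseline groups, group means.

The scale-adjusted metric of city ``c`` for indicator ``i`` at census ``t``
is the vertical log-residual around that year's fitted allometry,

    D_i(t) = log10 Y_i(t) - [A_i(t) + beta_i(t) log10 N(t)].

``D > 0`` means the city sits above the law for its size.  Because the fitted
line passes through the centroid of the log pairs, both the perpendicular and
the vertical residuals average to zero over the cities entering the fit.
Cities are grouped by the sign of D at a baseline census (above: D > 0;
below: D <= 0, ties counting as below) and the group label is frozen across
years, so group trajectories track how the initially-exceptional cities
evolve relative to the law.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from ._stats import bootstrap_mean_ci, check_rng
from .allometry import AllometricFit, _prepare_log_pairs
from .exceptions import EmptyGroupError
from .io import CensusPanel, SamiTable

__all__ = [
    "compute_sami",
    "label_baseline_groups",
    "group_mean_ci",
    "group_summaries",
    "GroupSummary",
]


def compute_sami(
    panel: CensusPanel,
    fits: dict[tuple[str, int], AllometricFit],
    zero_policy: str = "drop",
) -> SamiTable:
    """Residuals of every (city, indicator, year) around its year's fit.

    A fit must exist for every indicator-year present in the panel; rows that
    were excluded from the fit stage (nonpositive indicator values) carry no
    residual.  Each D is computed against the same year's fitted parameters,
    never a pooled fit.
    """
    rows = []
    for indicator in panel.indicators:
        for year in panel.years:
            key = (indicator, year)
            if key not in fits:
                raise KeyError(f"no allometric fit for indicator-year {key}")
            fit = fits[key]
            x, y, city, _ = _prepare_log_pairs(panel, indicator, year, zero_policy)
            d = y - (fit.intercept + fit.exponent * x)
            rows.append(pd.DataFrame({
                "city_id": city, "indicator": indicator, "year": year, "D": d,
            }))
    return SamiTable(pd.concat(rows, ignore_index=True))


def label_baseline_groups(
    table: SamiTable, baseline_year: int, refresh: bool = False
) -> SamiTable:
    """Attach frozen above/below labels from the baseline year.

    ``above`` iff D(baseline) > 0, else ``below`` (a city exactly on the law
    is ``below``).  With ``refresh=True`` the label instead follows each
    year's own sign (non-default; the frozen variant is the headline
    analysis).  Cities absent at baseline get no label; their count is kept
    in ``label_counts``.
    """
    frame = table.frame.copy()
    if refresh:
        frame["baseline_label"] = np.where(frame["D"] > 0, "above", "below")
        counts = {"above": int((frame["baseline_label"] == "above").sum()),
                  "below": int((frame["baseline_label"] == "below").sum()),
                  "missing_at_baseline": 0}
        return SamiTable(frame, counts)
    base = frame[frame["year"] == baseline_year]
    if base.empty:
        raise KeyError(f"baseline year {baseline_year} not present in table")
    label = np.where(base["D"] > 0, "above", "below")
    key = pd.MultiIndex.from_frame(base[["city_id", "indicator"]])
    mapping = pd.Series(label, index=key)
    frame_key = pd.MultiIndex.from_frame(frame[["city_id", "indicator"]])
    frame["baseline_label"] = mapping.reindex(frame_key).to_numpy()
    n_missing = int(frame["baseline_label"].isna().sum())
    counts = {
        "above": int((mapping == "above").sum()),
        "below": int((mapping == "below").sum()),
        "missing_at_baseline": n_missing,
    }
    return SamiTable(frame, counts)


@dataclass
class GroupSummary:
    """Mean scale-adjusted metric of one group at one census, with 95% CI."""

    indicator: str
    group: str
    year: int
    mean_D: float
    ci_low: float
    ci_high: float
    n_cities: int


def group_mean_ci(
    table: SamiTable,
    indicator: str,
    year: int,
    group: str,
    n_boot: int = 10_000,
    seed=None,
) -> GroupSummary:
    """Percentile-bootstrap 95% CI for a group's mean D at one census."""
    frame = table.frame
    if "baseline_label" not in frame.columns:
        raise ValueError("table has no baseline labels; call label_baseline_groups first")
    sel = frame[
        (frame["indicator"] == indicator)
        & (frame["year"] == year)
        & (frame["baseline_label"] == group)
    ]
    if sel.empty:
        raise EmptyGroupError(f"no cities in group {group!r} for {indicator} {year}")
    vals = sel["D"].to_numpy(dtype=float)
    mean, lo, hi = bootstrap_mean_ci(vals, n_boot=n_boot, rng=check_rng(seed))
    return GroupSummary(indicator, group, year, mean, lo, hi, vals.size)


def group_summaries(
    table: SamiTable, n_boot: int = 10_000, seed=None
) -> pd.DataFrame:
    """Group-mean table over all indicators, groups and years."""
    rng = check_rng(seed)
    rows = []
    for indicator in table.indicators:
        for group in ("above", "below"):
            for year in table.years:
                try:
                    s = group_mean_ci(table, indicator, year, group,
                                      n_boot=n_boot, seed=rng)
                except EmptyGroupError:
                    continue
                rows.append({
                    "indicator": s.indicator, "group": s.group, "year": s.year,
                    "mean": s.mean_D, "ci_low": s.ci_low, "ci_high": s.ci_high,
                    "n": s.n_cities,
                })
    return pd.DataFrame(rows)
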