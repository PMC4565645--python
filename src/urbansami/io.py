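"""Tabular input/output for census panels, scale-adjusted metric tables,
coordinates, and GeoJSON change maps.

Dialect: UTF-8, comma-separated, header row, ``.`` decimal mark.  City
identifiers are always read and written as strings so that zero-padded
municipality codes (IBGE style) survive a round trip.  Numeric columns are
written with 12 significant digits, which makes read-after-write lossless at
that precision.  Lines starting with ``#`` are metadata comments and are
ignored by every reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError

#: Canonical indicator names, in the fixed alphabetical order used by every
#: matrix and serialization in the package.
INDICATORS = (
    "child_labor",
    "elderly_population",
    "family_income",
    "female_population",
    "homicides",
    "illiteracy",
    "male_population",
    "unemployment",
)

_PANEL_KEY_COLUMNS = ("city_id", "city_name", "state", "year", "population")
_FLOAT_FMT = "%.12g"


@dataclass
class CensusPanel:
    """City x census-year table of population and indicator values.

    ``frame`` is wide: one row per (city_id, year) with columns
    ``city_id, city_name, state, year, population`` plus one column per
    indicator.  Missing indicator cells are NaN and are dropped per-analysis;
    the "complete" subset (every indicator present in every year) mirrors the
    complete-case filter used for the headline pipeline.
    """

    frame: pd.DataFrame
    indicators: tuple[str, ...] = INDICATORS
    n_dropped_missing_population: int = 0
    n_incomplete_rows: int = 0

    def __post_init__(self) -> None:
        self.indicators = tuple(self.indicators)
        dup = self.frame.duplicated(subset=["city_id", "year"])
        if dup.any():
            pair = self.frame.loc[dup.idxmax(), ["city_id", "year"]]
            raise IntegrityError(
                f"duplicate (city_id, year) pair: ({pair['city_id']}, {pair['year']})"
            )
        if (self.frame["population"] <= 0).any():
            raise IntegrityError("population must be > 0 for every retained row")

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    @property
    def city_ids(self) -> list[str]:
        return sorted(self.frame["city_id"].unique().tolist())

    def complete_city_ids(self) -> list[str]:
        """Cities with all configured indicators present in all years."""
        years = self.years
        ok = []
        cols = list(self.indicators)
        grouped = self.frame.groupby("city_id")
        for city, sub in grouped:
            if len(sub) == len(years) and sub[cols].notna().all().all():
                ok.append(city)
        return sorted(ok)

    @property
    def n_complete_cities(self) -> int:
        return len(self.complete_city_ids())

    def complete_subset(self) -> "CensusPanel":
        keep = set(self.complete_city_ids())
        sub = self.frame[self.frame["city_id"].isin(keep)].reset_index(drop=True)
        return CensusPanel(sub, self.indicators)

    def subset(self, year: int) -> pd.DataFrame:
        if year not in self.years:
            raise KeyError(f"year {year} not present in panel (have {self.years})")
        return self.frame[self.frame["year"] == year]


@dataclass
class CoordinateTable:
    """Per-city geographic coordinates in decimal degrees."""

    frame: pd.DataFrame  # columns: city_id, latitude, longitude

    def __post_init__(self) -> None:
        f = self.frame
        if f["city_id"].duplicated().any():
            raise IntegrityError("duplicate city_id in coordinate table")
        if not f["latitude"].between(-90, 90).all():
            raise IntegrityError("latitude outside [-90, 90]")
        if not f["longitude"].between(-180, 180).all():
            raise IntegrityError("longitude outside [-180, 180]")

    def lookup(self) -> dict[str, tuple[float, float]]:
        return {
            str(r.city_id): (float(r.latitude), float(r.longitude))
            for r in self.frame.itertuples()
        }


@dataclass
class SamiTable:
    """Long table of scale-adjusted metrics: one row per (city, indicator, year).

    ``frame`` columns: ``city_id, indicator, year, D`` and optionally
    ``baseline_label`` in {"above", "below"} frozen per (city_id, indicator).
    """

    frame: pd.DataFrame
    label_counts: dict = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    @property
    def indicators(self) -> list[str]:
        return sorted(self.frame["indicator"].unique().tolist())

    def pivot(self, year: int) -> pd.DataFrame:
        """Cities x indicators matrix of D at one year."""
        sub = self.frame[self.frame["year"] == year]
        return sub.pivot(index="city_id", columns="indicator", values="D")

    def series(self, indicator: str, year: int) -> pd.Series:
        sub = self.frame[
            (self.frame["indicator"] == indicator) & (self.frame["year"] == year)
        ]
        return sub.set_index("city_id")["D"]


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def _write_frame(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_lines(metadata))
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_census_panel(
    path,
    indicators: tuple[str, ...] | None = None,
    long_format: bool = False,
) -> CensusPanel:
    """Read a census panel CSV.

    The wide layout (default) has one column per indicator; the long layout
    (``long_format=True``) has columns ``indicator`` and ``value`` and is
    pivoted on read.  Rows with missing population are dropped and counted;
    rows with a missing indicator cell are kept (NaN) but counted as
    incomplete and excluded from the complete-city subset.
    """
    indicators = tuple(indicators) if indicators is not None else INDICATORS
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"city_id": str}, comment="#")
    if long_format:
        missing = [c for c in ("city_id", "year", "population", "indicator", "value") if c not in df.columns]
        if missing:
            raise FormatError(f"long-format panel missing column(s): {', '.join(missing)}")
        for c in ("city_name", "state"):
            if c not in df.columns:
                df[c] = ""
        df = (
            df.pivot_table(
                index=["city_id", "city_name", "state", "year", "population"],
                columns="indicator",
                values="value",
                aggfunc="first",
            )
            .reset_index()
        )
        df.columns.name = None
    missing = [c for c in _PANEL_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"census panel missing mandatory column(s): {', '.join(missing)}")
    missing_ind = [c for c in indicators if c not in df.columns]
    if missing_ind:
        raise FormatError(f"census panel missing indicator column(s): {', '.join(missing_ind)}")
    present_ind = [c for c in df.columns if c not in _PANEL_KEY_COLUMNS]
    extra = [c for c in present_ind if c not in indicators]
    if extra:
        df = df.drop(columns=extra)

    n_before = len(df)
    df = df[df["population"].notna() & (df["population"] > 0)].copy()
    n_dropped_pop = n_before - len(df)
    df["year"] = df["year"].astype(int)
    for c in indicators:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    incomplete = df[list(indicators)].isna().any(axis=1)
    panel = CensusPanel(
        df.reset_index(drop=True),
        indicators,
        n_dropped_missing_population=n_dropped_pop,
        n_incomplete_rows=int(incomplete.sum()),
    )
    return panel


def write_census_panel(panel: CensusPanel, path, metadata: dict | None = None) -> None:
    cols = list(_PANEL_KEY_COLUMNS) + list(panel.indicators)
    _write_frame(panel.frame[cols], path, metadata)


def read_sami_table(path, column_map: dict[str, str] | None = None) -> SamiTable:
    """Read a SAMI table (CSV, or .xlsx for supplementary-dataset-style spreadsheets).

    ``column_map`` renames user columns to the canonical
    ``city_id, indicator, year, D`` (plus optional ``baseline_label``); the
    supplementary dataset's exact header is not standardized, so a map must be
    supplied for non-canonical files.  Wide spreadsheets (one column per
    indicator-year) should be reshaped by the caller or read via
    :func:`read_sami_wide`.
    """
    path = Path(path)
    # read everything as text first so identifier columns keep leading
    # zeros regardless of what the user's column map calls them
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    required = ("city_id", "indicator", "year", "D")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"SAMI table missing column(s): {', '.join(missing)}")
    d_numeric = pd.to_numeric(df["D"], errors="coerce")
    bad = d_numeric.isna() & df["D"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"non-numeric D value at data row {row + 1}")
    df["D"] = d_numeric
    df["year"] = df["year"].astype(int)
    df["city_id"] = df["city_id"].astype(str)
    keep = ["city_id", "indicator", "year", "D"]
    if "baseline_label" in df.columns:
        keep.append("baseline_label")
    return SamiTable(df[keep].reset_index(drop=True))


def read_sami_wide(path, id_column: str = "city_id") -> SamiTable:
    """Read a wide precomputed-metrics sheet with columns like ``<indicator>_<year>``."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, dtype={id_column: str})
    else:
        df = pd.read_csv(path, dtype={id_column: str}, comment="#")
    value_cols = [c for c in df.columns if c != id_column]
    records = []
    for c in value_cols:
        name, _, year = c.rpartition("_")
        if not name or not year.isdigit():
            raise FormatError(f"cannot parse indicator-year column name '{c}'")
        sub = df[[id_column, c]].rename(columns={id_column: "city_id", c: "D"})
        sub["indicator"] = name
        sub["year"] = int(year)
        records.append(sub)
    out = pd.concat(records, ignore_index=True)[["city_id", "indicator", "year", "D"]]
    return SamiTable(out.dropna(subset=["D"]).reset_index(drop=True))


def write_sami_table(table: SamiTable, path, metadata: dict | None = None) -> None:
    if table.frame.empty:
        raise ValueError("refusing to write an empty SAMI table")
    _write_frame(table.frame, path, metadata)


def read_coordinates(path) -> CoordinateTable:
    df = pd.read_csv(path, dtype={"city_id": str}, comment="#")
    missing = [c for c in ("city_id", "latitude", "longitude") if c not in df.columns]
    if missing:
        raise FormatError(f"coordinate table missing column(s): {', '.join(missing)}")
    return CoordinateTable(df.reset_index(drop=True))


def write_coordinates(coords: CoordinateTable, path, metadata: dict | None = None) -> None:
    _write_frame(coords.frame, path, metadata)


def write_change_geojson(
    changes: pd.Series | dict,
    coords: CoordinateTable,
    path,
    scale: float = 1.0,
) -> list[str]:
    """Write an RFC 7946 point-feature collection of per-city changes.

    ``changes`` maps city_id -> delta (change in the scale-adjusted metric).
    Each feature carries ``city_id``, ``delta``, ``radius = scale * |delta|``
    and ``sign`` ("increase" for delta > 0, "decrease" otherwise; a zero
    change counts as a decrease by convention).  Cities without coordinates
    are skipped and returned, not raised.
    """
    if isinstance(changes, dict):
        changes = pd.Series(changes)
    lookup = coords.lookup()
    features = []
    skipped: list[str] = []
    for city_id, delta in changes.items():
        city_id = str(city_id)
        if city_id not in lookup:
            skipped.append(city_id)
            continue
        lat, lon = lookup[city_id]
        delta = float(delta)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": {
                    "city_id": city_id,
                    "delta": delta,
                    "radius": scale * abs(delta),
                    "sign": "increase" if delta > 0 else "decrease",
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(collection, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return skipped
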