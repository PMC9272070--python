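"""Per-climate-cell daily driver series and bilinear downscaling.

A :class:`ClimateSeriesSet` holds daily values of the three drivers
(surface temperature in °C, contact water in kg m⁻², relative humidity
upper ground in %) for every climate cell over a span of 364-day model
years.  Years can be resampled trend-preservingly by permuting whole
years within disjoint 20-year blocks — the same permutation for every
cell, so regional weather fronts stay spatially coherent.  Daily values
are downscaled to grassland cells with the landscape's bilinear weights.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .constants import DAYS_PER_YEAR, DRIVERS
from .landscape import Landscape

__all__ = [
    "ClimateSeriesSet",
    "DriverSnapshot",
    "resample_years",
    "interpolate_day",
    "read_climate_csv",
    "write_climate_csv",
]


class ClimateSeriesSet:
    """Daily driver series for a set of climate cells.

    ``data`` has shape ``(n_cells, n_years, 364, 3)`` with the driver
    axis ordered (temperature, contact_water, humidity).
    """

    def __init__(self, cell_ids, years, data: np.ndarray):
        self.cell_ids = np.asarray(cell_ids, dtype=int)
        self.years = np.asarray(years, dtype=int)
        data = np.asarray(data, dtype=float)
        expected = (len(self.cell_ids), len(self.years), DAYS_PER_YEAR, len(DRIVERS))
        if data.shape != expected:
            raise ValueError(f"data shape {data.shape} != expected {expected}")
        hum = data[..., DRIVERS.index("humidity")]
        if np.any((hum < 0) | (hum > 100)):
            raise ValueError("humidity values outside [0, 100]")
        if np.any(data[..., DRIVERS.index("contact_water")] < 0):
            raise ValueError("contact water values below 0")
        self.data = data
        self._index_of = {int(c): i for i, c in enumerate(self.cell_ids)}

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_days(self) -> int:
        return self.n_years * DAYS_PER_YEAR

    def cell_index(self, cell_id: int) -> int:
        try:
            return self._index_of[int(cell_id)]
        except KeyError:
            raise KeyError(f"no climate series for cell {cell_id}") from None

    def day_values(self, day: int) -> np.ndarray:
        """(n_cells, 3) driver values at absolute day index (0-based)."""
        if not 0 <= day < self.n_days:
            raise IndexError(f"day {day} outside series span of {self.n_days}")
        y, d = divmod(day, DAYS_PER_YEAR)
        return self.data[:, y, d, :]

    def flat(self) -> np.ndarray:
        """(n_cells, n_days, 3) view of the full series."""
        return self.data.reshape(len(self.cell_ids), self.n_days, len(DRIVERS))


class DriverSnapshot:
    """Interpolated driver values at every grassland cell for one day.

    ``values`` has shape ``(n_grassland, 3)``, rows ordered like
    ``landscape.grassland_ids``.
    """

    def __init__(self, day: int, cell_ids: np.ndarray, values: np.ndarray):
        self.day = day
        self.cell_ids = cell_ids
        self.values = values

    def at(self, cell_id: int, row_of) -> np.ndarray:
        return self.values[row_of(cell_id)]


def resample_years(
    series: ClimateSeriesSet, window_years: int = 20, seed=None
) -> ClimateSeriesSet:
    """Permute years within disjoint consecutive blocks of ``window_years``.

    Blocks are aligned to the series start; the last block may be short.
    One permutation is drawn per block and applied jointly to all cells
    and drivers, so years move as spatially coherent units and block
    means of every driver are conserved.
    """
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    rng = np.random.default_rng(seed)
    n = series.n_years
    perm = np.arange(n)
    for start in range(0, n, window_years):
        stop = min(start + window_years, n)
        block = np.arange(start, stop)
        perm[start:stop] = rng.permutation(block)
    return ClimateSeriesSet(
        series.cell_ids, series.years, series.data[:, perm, :, :]
    )


def interpolate_day(
    series: ClimateSeriesSet, landscape: Landscape, day: int
) -> DriverSnapshot:
    """Bilinearly interpolate one day's drivers to every grassland cell.

    Per grassland cell the value is the weighted sum of the enclosing
    climate cells' same-day values; the result is exact for fields
    linear in x and y and always lies in the convex hull of the
    contributing values.
    """
    clim_vals = series.day_values(day)  # (n_cells, 3) ordered like series
    n_clim = landscape.climate_spec.n_cells
    # reorder into landscape climate-id order
    grid_vals = np.empty((n_clim, len(DRIVERS)))
    grid_vals.fill(np.nan)
    for cid in range(n_clim):
        if cid in series._index_of:
            grid_vals[cid] = clim_vals[series.cell_index(cid)]
    needed = {cid for entries in landscape.weights.values() for cid, _d, _w in entries}
    missing = [cid for cid in needed if np.isnan(grid_vals[cid]).any()]
    if missing:
        raise ValueError(f"missing climate series for mapped cells {sorted(missing)}")
    values = landscape.weight_matrix @ np.nan_to_num(grid_vals)
    return DriverSnapshot(day, landscape.grassland_ids, values)


# -- input/output ------------------------------------------------------


def write_climate_csv(series: ClimateSeriesSet, path) -> None:
    """Write the series in long form: climate_id, year, day, driver, value."""
    n_cells, n_years = len(series.cell_ids), series.n_years
    cell = np.repeat(series.cell_ids, n_years * DAYS_PER_YEAR * len(DRIVERS))
    year = np.tile(np.repeat(series.years, DAYS_PER_YEAR * len(DRIVERS)), n_cells)
    day = np.tile(
        np.repeat(np.arange(1, DAYS_PER_YEAR + 1), len(DRIVERS)), n_cells * n_years
    )
    driver = np.tile(np.array(DRIVERS), n_cells * n_years * DAYS_PER_YEAR)
    pd.DataFrame(
        {
            "climate_id": cell,
            "year": year,
            "day": day,
            "driver": driver,
            "value": series.data.ravel(),
        }
    ).to_csv(path, index=False)


def read_climate_csv(path) -> ClimateSeriesSet:
    """Read a long-form climate CSV; order-independent and validated.

    Day-of-year must lie in 1..364; day 365/366 rows (leap or calendar
    overhang in real data) are dropped with a warning.  Missing days or
    duplicate (cell, year, day, driver) keys are errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"climate_id", "year", "day", "driver", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"climate CSV missing columns: {sorted(missing_cols)}")
    overhang = df["day"] > DAYS_PER_YEAR
    if overhang.any():
        warnings.warn(
            f"dropping {int(overhang.sum())} rows with day > {DAYS_PER_YEAR} "
            "(model years have 364 days)",
            stacklevel=2,
        )
        df = df[~overhang]
    if (df["day"] < 1).any():
        raise ValueError("day-of-year values below 1")
    unknown = set(df["driver"].unique()) - set(DRIVERS)
    if unknown:
        raise ValueError(f"unknown drivers in climate CSV: {sorted(unknown)}")
    dup = df.duplicated(subset=["climate_id", "year", "day", "driver"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValueError(
            f"duplicate climate record: cell {bad['climate_id']} year "
            f"{bad['year']} day {bad['day']} driver {bad['driver']}"
        )
    cells = np.sort(df["climate_id"].unique())
    years = np.sort(df["year"].unique())
    data = np.full(
        (len(cells), len(years), DAYS_PER_YEAR, len(DRIVERS)), np.nan
    )
    ci = {c: i for i, c in enumerate(cells)}
    yi = {y: i for i, y in enumerate(years)}
    di = {d: i for i, d in enumerate(DRIVERS)}
    data[
        df["climate_id"].map(ci).to_numpy(),
        df["year"].map(yi).to_numpy(),
        df["day"].to_numpy() - 1,
        df["driver"].map(di).to_numpy(),
    ] = df["value"].to_numpy()
    if np.isnan(data).any():
        nan_cells = cells[np.isnan(data).any(axis=(1, 2, 3))]
        raise ValueError(
            f"incomplete climate series (missing days) for cells {list(nan_cells)}"
        )
    return ClimateSeriesSet(cells, years, data)
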