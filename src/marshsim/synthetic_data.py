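"""Synthetic climate series, landscapes and ready-to-run scenario bundles.

Everything the simulator consumes can be generated here so that runs and
tests need no external downloads.  The climate generator emulates the
statistical structure of regional climate projections for a north
German lowland: a seasonal temperature sinusoid with a linear warming
trend, a north–south spatial gradient and shared AR(1) weather noise;
seasonal contact water with a late-summer minimum (so egg drought stress
is exercisable); and seasonal relative humidity.  Three severity
scenarios are provided — ``FF`` (full force mitigation), ``MOD``
(moderate) and ``BAU`` (business as usual) — ordered by warming trend.

The landscape generator produces lattices of controllable grassland
cover and spatial clustering by thresholding a smoothed Gaussian random
field at the cover quantile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .climate import ClimateSeriesSet, write_climate_csv
from .constants import DAYS_PER_YEAR, SIZE_CLIM, SIZE_HAB
from .landscape import ClimateGridSpec, build_landscape, write_landscape_csv

__all__ = [
    "ClimateScenarioSpec",
    "LandscapeSpec",
    "scenario_spec",
    "gen_climate",
    "gen_landscape",
    "gen_scenario_bundle",
]

#: Default warming trends (°C per 60 years) for the three severity
#: scenarios.  Synthetic stand-ins of increasing severity, not values
#: taken from any climate model.
SCENARIO_TRENDS = {"FF": 0.5, "MOD": 1.5, "BAU": 3.5}

#: Day-of-year of the summer temperature maximum (mid-July).
_TEMP_PEAK_DAY = 196
#: Day-of-year of the contact-water minimum (mid/late August).
_WATER_MIN_DAY = 227


@dataclass
class ClimateScenarioSpec:
    """Parameters of one synthetic climate severity scenario."""

    tag: str = "MOD"
    mean_temp_c: float = 9.0
    warming_trend_c_per_60y: float = 1.5
    seasonal_amplitude_c: float = 8.5
    gradient_c_per_100km: float = 1.0  # cooler toward the north
    ar_sigma: float = 0.5
    ar_phi: float = 0.7
    water_base_kg_m2: float = 3.0
    water_seasonal_amp: float = 2.0
    water_sigma: float = 0.3
    humidity_base_pct: float = 80.0
    humidity_seasonal_amp: float = 10.0
    humidity_sigma: float = 2.0

    def validate(self) -> None:
        for name in ("ar_sigma", "water_sigma", "humidity_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ar_phi < 1:
            raise ValueError("ar_phi must lie in [0, 1)")
        if self.seasonal_amplitude_c < 0 or self.water_seasonal_amp < 0:
            raise ValueError("seasonal amplitudes must be >= 0")


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic habitat lattice."""

    nx: int = 20
    ny: int = 20
    cover: float = 0.5
    clustering: float = 0.0  # 0 = spatially random, 1 = single blob
    seed: int = 0

    def validate(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("lattice must be at least 2x2")
        if not 0.0 <= self.cover <= 1.0:
            raise ValueError("cover must lie in [0, 1]")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must lie in [0, 1]")


def scenario_spec(tag: str, **overrides) -> ClimateScenarioSpec:
    """Preset scenario spec for one of the severity tags FF/MOD/BAU."""
    tag = tag.upper()
    if tag not in SCENARIO_TRENDS:
        raise ValueError(f"unknown scenario tag {tag!r}; expected FF, MOD or BAU")
    spec = ClimateScenarioSpec(
        tag=tag, warming_trend_c_per_60y=SCENARIO_TRENDS[tag], **overrides
    )
    spec.validate()
    return spec


def gen_climate(
    spec: ClimateScenarioSpec,
    climate_spec: ClimateGridSpec,
    years,
    seed=None,
) -> ClimateSeriesSet:
    """Generate daily driver series for every cell of a climate lattice.

    Temperature per cell and day is mean + seasonal sinusoid + linear
    trend + north–south gradient + shared AR(1) noise.  Contact water
    and humidity are seasonal with their own (shared) Gaussian noise,
    clipped to physical ranges.  The noise series are shared across
    cells so regional weather stays spatially coherent.
    """
    spec.validate()
    years = np.asarray(years, dtype=int)
    if len(years) < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    n_years = len(years)
    n_days = n_years * DAYS_PER_YEAR
    n_cells = climate_spec.n_cells

    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    t = np.arange(n_days)

    seasonal = spec.seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - _TEMP_PEAK_DAY) / DAYS_PER_YEAR
    )
    trend = spec.warming_trend_c_per_60y * t / (60.0 * DAYS_PER_YEAR)

    # shared AR(1) weather noise
    eps = rng.normal(0.0, spec.ar_sigma, size=n_days)
    noise = np.empty(n_days)
    acc = 0.0
    phi = spec.ar_phi
    for i in range(n_days):
        acc = phi * acc + eps[i]
        noise[i] = acc

    water_season = spec.water_base_kg_m2 + spec.water_seasonal_amp * np.cos(
        2 * np.pi * (doy - (_WATER_MIN_DAY - DAYS_PER_YEAR // 2)) / DAYS_PER_YEAR
    )
    water = np.clip(
        water_season + rng.normal(0.0, spec.water_sigma, size=n_days), 0.0, None
    )
    humidity = np.clip(
        spec.humidity_base_pct
        + spec.humidity_seasonal_amp
        * np.cos(2 * np.pi * (doy - 15) / DAYS_PER_YEAR)
        + rng.normal(0.0, spec.humidity_sigma, size=n_days),
        0.0,
        100.0,
    )

    data = np.empty((n_cells, n_years, DAYS_PER_YEAR, 3))
    base_temp = spec.mean_temp_c + seasonal + trend + noise
    for cid in range(n_cells):
        iy = cid // climate_spec.nx
        _cx, cy = climate_spec.center(cid % climate_spec.nx, iy)
        offset = -spec.gradient_c_per_100km * cy / 100_000.0
        data[cid, ..., 0] = (base_temp + offset).reshape(n_years, DAYS_PER_YEAR)
        data[cid, ..., 1] = water.reshape(n_years, DAYS_PER_YEAR)
        data[cid, ..., 2] = humidity.reshape(n_years, DAYS_PER_YEAR)

    return ClimateSeriesSet(np.arange(n_cells), years, data)


def gen_landscape(spec: LandscapeSpec) -> np.ndarray:
    """Generate a boolean habitat lattice of given cover and clustering.

    White noise is smoothed with a Gaussian kernel whose width grows
    with the clustering parameter, then thresholded at the cover
    quantile so the realised grassland fraction matches the target to
    within one cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    field = rng.normal(size=(spec.ny, spec.nx))
    if spec.clustering > 0:
        sigma = spec.clustering * 0.25 * min(spec.nx, spec.ny)
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="wrap")
    n = spec.nx * spec.ny
    k = int(round(spec.cover * n))
    if k <= 0:
        return np.zeros((spec.ny, spec.nx), dtype=bool)
    if k >= n:
        return np.ones((spec.ny, spec.nx), dtype=bool)
    threshold = np.partition(field.ravel(), n - k)[n - k]
    grid = field >= threshold
    # exact count despite possible float ties
    excess = int(grid.sum()) - k
    if excess > 0:
        idx = np.flatnonzero(grid.ravel() & (field.ravel() == threshold))[:excess]
        flat = grid.ravel()
        flat[idx] = False
        grid = flat.reshape(spec.ny, spec.nx)
    return grid


def gen_scenario_bundle(
    climate_scenario: ClimateScenarioSpec,
    landscape_spec: LandscapeSpec,
    schedule_name: str,
    seed=0,
    years=None,
    out_dir: str | Path | None = None,
):
    """Generate a self-consistent (landscape, climate series, config) triple.

    The climate lattice is sized to cover the habitat lattice.  If
    ``out_dir`` is given, the landscape CSV, climate CSV and a JSON
    config are written there.
    """
    from .disturbance import builtin_schedules  # local import avoids a cycle

    if schedule_name not in builtin_schedules():
        raise ValueError(f"unknown mowing schedule {schedule_name!r}")
    if years is None:
        years = np.arange(2020, 2080)
    habitat = gen_landscape(landscape_spec)
    cnx = max(1, int(np.ceil(landscape_spec.nx * SIZE_HAB / SIZE_CLIM)))
    cny = max(1, int(np.ceil(landscape_spec.ny * SIZE_HAB / SIZE_CLIM)))
    climate_grid = ClimateGridSpec(nx=cnx, ny=cny)
    landscape = build_landscape(habitat, climate_grid)
    series = gen_climate(climate_scenario, climate_grid, years, seed=seed)
    config = {
        "scenario": climate_scenario.tag,
        "mowing_schedule": schedule_name,
        "seed": int(seed),
        "years": int(len(years)),
        "start_year": int(years[0]),
        "climate_grid": {"nx": cnx, "ny": cny, "size": SIZE_CLIM},
        "climate_scenario": asdict(climate_scenario),
        "landscape": asdict(landscape_spec),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_landscape_csv(landscape, out / "landscape.csv")
        write_climate_csv(series, out / "climate.csv")
        with open(out / "config.json", "w") as fh:
            json.dump(config, fh, indent=2, sort_keys=True)
    return landscape, series, config
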