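"""Dispersal-success evaluation parameters and scenario comparisons.

Four yearly evaluation parameters summarise a run at the end of each
364-day model year, using only cells inhabited at that point (when the
population typically sits in the diapause stage, so size and density
are reported in eggs):

1. *dispersal distance* — metres from the source cell to the farthest
   occupied cell;
2. *established distance* — metres to the farthest *established* cell,
   where a cell counts as established in a year if its imago density
   reached at least 0.002 individuals m⁻² at any point during that
   year; cells colonised directly from the source by a long-distance
   jump are excluded from the maximum to avoid misleading outliers;
3. *population size* — total eggs/individuals over established cells;
4. *population density* — mean density over established cells.

The module also provides scenario-delta summaries (mean absolute yearly
difference of a metric between two climate scenarios) and cross-region
rank correlations between evaluation parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ESTABLISHED_IMAGO_DENSITY",
    "YearlyMetrics",
    "is_established",
    "yearly_snapshot",
    "establishment_rate",
    "scenario_delta",
    "cross_region_correlation",
    "metrics_to_frame",
    "cell_map_frame",
]

#: Imago density (individuals m⁻²) at or above which a habitat counts
#: as established within a year.
ESTABLISHED_IMAGO_DENSITY = 0.002


@dataclass
class YearlyMetrics:
    """Evaluation parameters of one run-year."""

    year: int
    occupied_cells: int
    established_cells: set[int] = field(default_factory=set)
    max_dispersal_distance: float = 0.0
    max_established_distance: float = 0.0
    population_size: float = 0.0       # total eggs/individuals, established cells
    population_density: float = 0.0    # mean per-m² density, established cells


def is_established(
    year_max_imago_density: float,
    threshold: float = ESTABLISHED_IMAGO_DENSITY,
) -> bool:
    """Establishment test for one cell-year (inclusive at the threshold)."""
    return year_max_imago_density >= threshold


def yearly_snapshot(
    year: int,
    source_xy: tuple[float, float],
    occupied: dict[int, float],
    cell_xy,
    year_max_imago: dict[int, float],
    direct_ldd_cells: set[int],
    cell_area: float,
    threshold: float = ESTABLISHED_IMAGO_DENSITY,
) -> YearlyMetrics:
    """Compute one year's evaluation parameters.

    ``occupied`` maps inhabited cell ids to their year-end total
    density; ``cell_xy`` maps a cell id to its centre; ``year_max_imago``
    holds the running per-cell maximum of daily imago density over the
    year.  ``direct_ldd_cells`` are cells whose first colonisation was
    a long-distance jump straight from the source cell — they count as
    occupied/established but are dropped from the established-distance
    maximum.
    """
    m = YearlyMetrics(year=year, occupied_cells=len(occupied))
    if not occupied:
        return m
    sx, sy = source_xy
    established: list[int] = []
    for cid, density in occupied.items():
        cx, cy = cell_xy(cid)
        dist = float(np.hypot(cx - sx, cy - sy))
        m.max_dispersal_distance = max(m.max_dispersal_distance, dist)
        if is_established(year_max_imago.get(cid, 0.0), threshold):
            established.append(cid)
            if cid not in direct_ldd_cells:
                m.max_established_distance = max(m.max_established_distance, dist)
    m.established_cells = set(established)
    if established:
        densities = np.array([occupied[c] for c in established])
        m.population_size = float((densities * cell_area).sum())
        m.population_density = float(densities.mean())
    return m


def establishment_rate(mean_max_established_m: float, years: int) -> int:
    """Mean establishment advance in metres per 2-year interval.

    E.g. 14 000 m over 60 years → 467 m per 2 years, the scale on which
    field recolonisation distances are usually reported.
    """
    if years <= 0 or years % 2:
        raise ValueError("years must be positive and even")
    return int(round(mean_max_established_m / (years / 2)))


def scenario_delta(series_a: np.ndarray, series_b: np.ndarray):
    """Mean absolute yearly delta of a metric between two scenarios.

    ``series_a``/``series_b`` are (n_replicates, n_years) arrays of the
    same metric under scenarios A and B.  Per replicate the yearly
    signed deltas A − B are taken; reported are the replicate mean of
    the absolute yearly delta and which scenario's overall mean is
    higher (``"A"``, ``"B"`` or ``None`` on a tie).  Signed deltas of
    alternating sign can cancel in the mean while the absolute delta
    stays large — both are returned.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"series shapes differ: {a.shape} vs {b.shape}")
    signed = a - b
    mean_abs = float(np.mean(np.abs(signed)))
    mean_signed = float(np.mean(signed))
    if mean_signed > 0:
        favored = "A"
    elif mean_signed < 0:
        favored = "B"
    else:
        favored = None
    return mean_abs, mean_signed, favored


def cross_region_correlation(values_a, values_b) -> float:
    """Spearman rank correlation of two evaluation parameters across regions.

    Returns NaN when either side has zero variance (the coefficient is
    undefined then).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-d value arrays required")
    if len(a) < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    rho, _p = stats.spearmanr(a, b)
    return float(rho)


def metrics_to_frame(metrics: list[YearlyMetrics], run_id: str = "run") -> pd.DataFrame:
    """Tabulate yearly metrics for CSV export."""
    return pd.DataFrame(
        {
            "run_id": run_id,
            "year": [m.year for m in metrics],
            "occupied_cells": [m.occupied_cells for m in metrics],
            "established_cells": [len(m.established_cells) for m in metrics],
            "max_dispersal_distance_m": [m.max_dispersal_distance for m in metrics],
            "max_established_distance_m": [m.max_established_distance for m in metrics],
            "population_size": [m.population_size for m in metrics],
            "population_density": [m.population_density for m in metrics],
        }
    )


def cell_map_frame(result, landscape) -> pd.DataFrame:
    """Per-cell map of a run's established cells, year by year.

    One row per (year, established cell) with the cell centre — the
    table behind distribution-map rendering.  The final year
    additionally carries the year-end total density per cell from the
    run's end state.
    """
    final_density = {
        cid: pop.total_density() for cid, pop in result.state.populations.items()
    }
    last_year = result.yearly[-1].year if result.yearly else None
    rows = []
    for m in result.yearly:
        for cid in sorted(m.established_cells):
            cx, cy = landscape.center_xy(cid)
            dens = final_density.get(cid) if m.year == last_year else None
            rows.append((m.year, cid, cx, cy, True, dens))
    return pd.DataFrame(
        rows,
        columns=["year", "cell_id", "x_m", "y_m", "established", "density"],
    )
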