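"""Run orchestration: initialisation, fixed daily ordering, replicates.

A run starts in the beginning of the first model year with a single
population — 0.725 eggs m⁻² in the diapause stage — placed in the
grassland cell closest to the geometric centre of a chosen climate
cell.  The source cell is always kept on the low-impact mowing schedule
M00 so it acts as an undisturbed dispersal source; every other cell
carries the configured schedule.  A 60-year run schedules exactly
60 × 364 = 21 840 daily steps and stops early only on global extinction.

The daily process ordering is fixed: interpolate drivers → apply mowing
(if the cell's schedule fires) → demographic stage/cohort update
(oviposition on the pre-mortality imago count, binomial deaths,
development accumulation, binomial maturation transfers, the diapause
calendar gate) → dispersal → activation of newly colonised cells.
Dispersal flows are buffered and applied synchronously at the end of
the dispersal phase, so arrivals take part in the model from the
following day and within-day chain dispersal is impossible.

Internally the engine keeps every cohort of every inhabited cell in
one set of flat arrays and performs each day's stochastic draws as a
handful of vectorised calls over them, in a canonical (colonisation
order, stage, cohort age) layout; one counter-based random stream
drives a whole replicate.  Results are therefore deterministic under a
fixed master seed and independent of any cell enumeration order.  Per
cell, daily effective rates over the whole horizon are precomputed at
colonisation, since they depend only on the interpolated drivers there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .climate import ClimateSeriesSet, resample_years
from .constants import CELL_AREA_M2, DAYS_PER_YEAR
from .dispersal import DispersalKernel, DispersalParams, _draw_removals, build_kernel
from .disturbance import MowingImpact, MowingSchedule, builtin_schedules
from .landscape import Landscape, Neighborhood, build_neighborhood, grassland_cover
from .lifecycle import (
    STAGE_ORDER,
    Population,
    StageSpec,
    diapause_gate,
    lmg_default,
    stage_rates_vector,
)
from .metrics import ESTABLISHED_IMAGO_DENSITY, YearlyMetrics, yearly_snapshot

__all__ = [
    "SimulationConfig",
    "RunState",
    "RunResult",
    "initialize_run",
    "step_day",
    "run",
    "run_replicates",
    "replicate_summary",
]

INITIAL_DIAPAUSE_DENSITY = 0.725  # eggs per m² at the source cell
SOURCE_SCHEDULE_ACRONYM = "M00"

_N_STAGES = len(STAGE_ORDER)
_IMAGO = STAGE_ORDER.index("imago")


@dataclass
class SimulationConfig:
    """Everything one simulation run needs."""

    landscape: Landscape
    series: ClimateSeriesSet
    source_climate_cell: int
    schedule: str | MowingSchedule = "M00"
    impact: MowingImpact = field(default_factory=MowingImpact)
    stage_table: dict[str, StageSpec] | None = None
    dispersal_params: DispersalParams = field(default_factory=DispersalParams)
    years: int = 60
    replicates: int = 10
    dispersal_enabled: bool = True
    master_seed: int = 0
    resample_window: int = 20
    initial_density: float = INITIAL_DIAPAUSE_DENSITY
    established_threshold: float = ESTABLISHED_IMAGO_DENSITY

    def __post_init__(self):
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.stage_table is None:
            self.stage_table = lmg_default()
        if isinstance(self.schedule, str):
            table = builtin_schedules()
            if self.schedule not in table:
                raise ValueError(f"unknown mowing schedule {self.schedule!r}")
            self.schedule = table[self.schedule]

    @property
    def scheduled_steps(self) -> int:
        return self.years * DAYS_PER_YEAR


class RunState:
    """Mutable state of one replicate run.

    Cohorts of all inhabited cells live in flat parallel arrays
    (``cellrow``, ``stage``, ``count``, ``dev``, ``age``); ``cellrow``
    indexes the table of ever-inhabited cells (``row_cells``), which
    only grows.  Only inhabited cells consume per-day work.
    """

    def __init__(self, config: SimulationConfig, replicate: int, source_cell: int,
                 clim_grid: np.ndarray):
        self.config = config
        self.replicate = replicate
        self.source_cell = source_cell
        self.day = 0  # daily steps executed so far
        self.rng = np.random.Generator(
            np.random.Philox(
                key=[(config.master_seed * 1_000_003 + replicate) & (2**63 - 1), 0]
            )
        )
        # flat cohort arrays, canonical order (appended chronologically)
        self.cellrow = np.empty(0, dtype=np.int64)
        self.stage = np.empty(0, dtype=np.int64)
        self.count = np.empty(0, dtype=np.int64)
        self.dev = np.empty(0, dtype=float)
        self.age = np.empty(0, dtype=np.int64)
        # ever-inhabited cell table
        self.row_cells: list[int] = []
        self._row_of: dict[int, int] = {}
        self._rate_tables: list[np.ndarray] = []   # per row: (n_days, 5, 3)
        self._mow_days: list[tuple[int, ...]] = []  # per row: firing days-of-year
        self.kernels: dict[int, DispersalKernel] = {}
        self.neighborhoods: dict[int, Neighborhood] = {}
        self.covers: dict[int, float] = {}
        self.year_max_imago = np.empty(0, dtype=float)  # per row, current year
        self.direct_ldd_cells: set[int] = set()
        self.dispersal_deaths = 0
        self.yearly: list[YearlyMetrics] = []
        self.extinct = False
        # (n_days, n_climate_cells, 3) resampled driver array in climate-grid order
        self.clim_grid = clim_grid
        self._mow_table = builtin_schedules()
        self._transfer_by_stage = np.array(
            [config.stage_table[s].transfer for s in STAGE_ORDER]
        )
        self._above_by_stage = np.array(
            [config.stage_table[s].aboveground for s in STAGE_ORDER]
        )

    # -- cell bookkeeping ----------------------------------------------

    def schedule_for(self, cell: int) -> MowingSchedule:
        if cell == self.source_cell:
            return self._mow_table[SOURCE_SCHEDULE_ACRONYM]
        return self.config.schedule

    def activate_cell(self, cell: int) -> int:
        """Row index of a cell, creating it on first colonisation."""
        row = self._row_of.get(cell)
        if row is None:
            row = len(self.row_cells)
            self._row_of[cell] = row
            self.row_cells.append(cell)
            self._rate_tables.append(self._build_rate_table(cell))
            self._mow_days.append(self.schedule_for(cell).event_days)
            self.year_max_imago = np.append(self.year_max_imago, 0.0)
        return row

    def _build_rate_table(self, cell: int) -> np.ndarray:
        """Daily effective rates of a cell over the whole horizon.

        Effective rates depend only on the interpolated drivers at the
        cell (persistence counters included — they are functions of the
        driver series alone), so the whole (n_days, stage, rate) table
        is computed once per cell.
        """
        w = self.config.landscape.weight_matrix[
            self.config.landscape.weight_row(cell)
        ]
        drivers = np.tensordot(self.clim_grid, w, axes=([1], [0]))  # (n_days, 3)
        persist = _persistence_counts(self.config.stage_table, drivers)
        table = np.empty((drivers.shape[0], _N_STAGES, 3))
        for si, name in enumerate(STAGE_ORDER):
            m, d, f = stage_rates_vector(
                self.config.stage_table[name], drivers, persist
            )
            table[:, si, 0] = m
            table[:, si, 1] = d
            table[:, si, 2] = f
        return table

    def cover_for(self, cell: int) -> float:
        c = self.covers.get(cell)
        if c is None:
            c = grassland_cover(
                self.config.landscape,
                self.config.landscape.center_xy(cell),
                self.config.dispersal_params.rad_disp,
            )
            self.covers[cell] = c
        return c

    def kernel_for(self, cell: int) -> DispersalKernel:
        """Dispersal setup of a cell: neighbourhood, cover and kernel."""
        k = self.kernels.get(cell)
        if k is None:
            nb = self.neighborhoods.get(cell)
            if nb is None:
                nb = build_neighborhood(
                    self.config.landscape, cell, self.config.dispersal_params.rad_disp
                )
                self.neighborhoods[cell] = nb
            base = self.config.stage_table["imago"].dispersal
            if not self.config.dispersal_enabled:
                base = 0.0
            k = build_kernel(
                cell, nb, self.cover_for(cell), self.config.dispersal_params,
                base_rate=base,
            )
            self.kernels[cell] = k
        return k

    def _append_cohorts(self, rows, stages, counts, devs=None, ages=None) -> None:
        k = len(rows)
        if k == 0:
            return
        self.cellrow = np.concatenate([self.cellrow, rows])
        self.stage = np.concatenate([self.stage, stages])
        self.count = np.concatenate([self.count, counts])
        self.dev = np.concatenate(
            [self.dev, devs if devs is not None else np.zeros(k)]
        )
        self.age = np.concatenate(
            [self.age, ages if ages is not None else np.zeros(k, dtype=np.int64)]
        )

    # -- inspection ----------------------------------------------------

    @property
    def populations(self) -> dict[int, Population]:
        """Materialised per-cell view of the flat cohort arrays."""
        pops: dict[int, Population] = {}
        for i in range(len(self.cellrow)):
            cell = self.row_cells[self.cellrow[i]]
            pop = pops.get(cell)
            if pop is None:
                pop = Population(cell)
                pops[cell] = pop
            pop.stages[STAGE_ORDER[self.stage[i]]].add_count(
                int(self.count[i]), age=int(self.age[i]), dev=float(self.dev[i])
            )
        return pops

    def occupied_cells(self) -> list[int]:
        rows = np.unique(self.cellrow[self.count > 0])
        return sorted(self.row_cells[r] for r in rows)

    def total_count(self) -> int:
        return int(self.count.sum())


@dataclass
class RunResult:
    """Outputs of one replicate run."""

    replicate: int
    yearly: list[YearlyMetrics]
    steps_executed: int
    scheduled_steps: int
    extinct: bool
    state: RunState

    def metrics_frame(self) -> pd.DataFrame:
        return metrics_mod.metrics_to_frame(
            self.yearly, run_id=f"rep{self.replicate}"
        )


def _source_cell(landscape: Landscape, climate_cell: int) -> int:
    """Grassland cell closest to a climate cell's geometric centre.

    Only grassland inside the climate cell's square qualifies; distance
    ties break on the lowest cell id.
    """
    spec = landscape.climate_spec
    ci, cj = climate_cell % spec.nx, climate_cell // spec.nx
    cx, cy = spec.center(ci, cj)
    half = spec.size / 2.0
    g = landscape.grassland_ids
    gx = landscape._centers_x[g]
    gy = landscape._centers_y[g]
    inside = (np.abs(gx - cx) <= half) & (np.abs(gy - cy) <= half)
    if not inside.any():
        raise ValueError(
            f"climate cell {climate_cell} contains no grassland cell"
        )
    d2 = (gx[inside] - cx) ** 2 + (gy[inside] - cy) ** 2
    cand = g[inside]
    best = cand[d2 == d2.min()]
    return int(best.min())


def _persistence_counts(
    stage_table: dict[str, StageSpec], drivers: np.ndarray
) -> dict[tuple[str, float], np.ndarray]:
    """Consecutive-days-below-threshold counters over a driver series.

    For every (driver, threshold) pair used by a persistence influence,
    returns the per-day count of consecutive preceding days (inclusive)
    the driver stayed below the threshold.
    """
    col = {"temperature": 0, "contact_water": 1, "humidity": 2}
    keys = {
        (infl.driver, infl.persistence_below)
        for stage in stage_table.values()
        for infl in stage.influences
        if infl.persistence_days is not None
    }
    out: dict[tuple[str, float], np.ndarray] = {}
    n = drivers.shape[0]
    t = np.arange(n)
    for driver, below in keys:
        b = drivers[:, col[driver]] < below
        last_false = np.maximum.accumulate(np.where(~b, t, -1))
        out[(driver, below)] = np.where(b, t - last_false, 0)
    return out


def _prepare_climate(config: SimulationConfig, replicate: int) -> np.ndarray:
    """Resample years for one replicate and lay the series out per day.

    Returns an (n_days, n_climate_cells, 3) array in climate-grid id
    order, validated against the configured horizon.
    """
    seed = np.random.SeedSequence([config.master_seed, replicate, 0xC11A])
    series = resample_years(config.series, config.resample_window, seed=seed)
    if series.n_days < config.scheduled_steps:
        raise ValueError(
            f"climate series covers {series.n_days} days but the run needs "
            f"{config.scheduled_steps}"
        )
    n_clim = config.landscape.climate_spec.n_cells
    flat = series.flat()  # (n_cells, n_days, 3)
    out = np.full((config.scheduled_steps, n_clim, 3), np.nan)
    for cid in range(n_clim):
        if int(cid) in series._index_of:
            out[:, cid, :] = flat[series.cell_index(cid), : config.scheduled_steps, :]
    needed = {
        cid
        for entries in config.landscape.weights.values()
        for cid, _d, _w in entries
    }
    missing = [c for c in needed if np.isnan(out[0, c]).any()]
    if missing:
        raise ValueError(f"missing climate series for mapped cells {sorted(missing)}")
    return np.nan_to_num(out)


def initialize_run(config: SimulationConfig, replicate: int = 0) -> RunState:
    """Place the initial population and build the run state."""
    source = _source_cell(config.landscape, config.source_climate_cell)
    clim = _prepare_climate(config, replicate)
    state = RunState(config, replicate, source, clim)
    row = state.activate_cell(source)
    from .lifecycle import to_count

    state._append_cohorts(
        np.array([row]),
        np.array([STAGE_ORDER.index("diapause")]),
        np.array([to_count(config.initial_density)], dtype=np.int64),
    )
    return state


def step_day(state: RunState) -> None:
    """Advance the run by one day in the fixed process ordering."""
    config = state.config
    t = state.day
    day_of_year = t % DAYS_PER_YEAR + 1
    rng = state.rng
    n_rows = len(state.row_cells)
    area = CELL_AREA_M2

    cellrow, stage, count, dev = state.cellrow, state.stage, state.count, state.dev

    # (2) mowing on cells whose schedule fires today
    firing = np.array(
        [day_of_year in days for days in state._mow_days], dtype=bool
    )
    if firing.any():
        factor = np.where(
            state._above_by_stage, 1.0 - config.impact.aboveground,
            1.0 - config.impact.belowground,
        )
        mask = firing[cellrow]
        if mask.any():
            count[mask] = np.floor(
                count[mask] * factor[stage[mask]] + 0.5
            ).astype(np.int64)

    # (1)+(3) daily effective rates, from the per-cell horizon tables
    rates = np.empty((n_rows, _N_STAGES, 3))
    for r in range(n_rows):
        rates[r] = state._rate_tables[r][t]
    for si, name in enumerate(STAGE_ORDER):
        window = config.stage_table[name].active_window
        if window is not None and not diapause_gate(day_of_year, window):
            rates[:, si, 1] = 0.0

    # (4a) oviposition from the pre-mortality imago head counts
    imago_mask = stage == _IMAGO
    imago_per_row = np.bincount(
        cellrow[imago_mask], weights=count[imago_mask], minlength=n_rows
    )
    lam = imago_per_row * rates[:, _IMAGO, 2]
    eggs = rng.poisson(lam) if lam.any() else np.zeros(n_rows, dtype=np.int64)

    # (4b) binomial deaths, development accumulation, maturation transfers;
    # ages advance here so cohorts created later today stay at age 0
    if len(count):
        state.age += 1
        mort = rates[cellrow, stage, 0]
        count -= rng.binomial(count, mort)
        dev += rates[cellrow, stage, 1]
        trans = state._transfer_by_stage[stage]
        mature = (dev >= 1.0) & (count > 0) & (trans > 0.0)
        if mature.any():
            moved = rng.binomial(count[mature], trans[mature])
            count[mature] -= moved
            sink = cellrow[mature] * _N_STAGES + (stage[mature] + 1)
            per_sink = np.bincount(sink, weights=moved, minlength=n_rows * _N_STAGES)
            nz = np.flatnonzero(per_sink)
            state._append_cohorts(
                nz // _N_STAGES, nz % _N_STAGES, per_sink[nz].astype(np.int64)
            )
    egg_rows = np.flatnonzero(eggs)
    if len(egg_rows):
        state._append_cohorts(
            egg_rows,
            np.zeros(len(egg_rows), dtype=np.int64),
            eggs[egg_rows].astype(np.int64),
        )

    # (5) dispersal: draws per source cell, flows buffered
    if config.dispersal_enabled:
        cellrow, stage, count = state.cellrow, state.stage, state.count
        imago_mask = stage == _IMAGO
        imago_rows = np.bincount(
            cellrow[imago_mask], weights=count[imago_mask], minlength=n_rows
        ).astype(np.int64)
        base = config.stage_table["imago"].dispersal
        arrivals_total: dict[int, int] = {}
        arrival_direct_ldd: set[int] = set()
        if base > 0.0 and imago_rows.any():
            emig = rng.binomial(imago_rows, base)
            for r in np.flatnonzero(emig):
                cell = state.row_cells[r]
                kernel = state.kernel_for(cell)
                m = int(emig[r])
                if kernel.n_targets:
                    probs = np.append(
                        kernel.p_disp, max(0.0, 1.0 - kernel.p_disp.sum())
                    )
                    alloc = rng.multinomial(m, probs / probs.sum())
                    state.dispersal_deaths += int(alloc[-1])
                    for tid, k in zip(kernel.target_ids, alloc[:-1]):
                        if k > 0:
                            tid = int(tid)
                            arrivals_total[tid] = arrivals_total.get(tid, 0) + int(k)
                            if cell == state.source_cell and kernel.is_ldd[
                                np.flatnonzero(kernel.target_ids == tid)[0]
                            ]:
                                arrival_direct_ldd.add(tid)
                else:
                    state.dispersal_deaths += m
                # remove emigrants from the source imago cohorts
                idx = np.flatnonzero((cellrow == r) & imago_mask)
                count[idx] -= _draw_removals(rng, count[idx], m)
        # (6) apply arrivals; newly colonised cells activate for later days
        if arrivals_total:
            rows, counts = [], []
            for tid in sorted(arrivals_total):
                known = tid in state._row_of
                rows.append(state.activate_cell(tid))
                counts.append(arrivals_total[tid])
                if not known and tid in arrival_direct_ldd:
                    state.direct_ldd_cells.add(tid)
            n_new = len(state.row_cells)
            if n_new > n_rows:
                n_rows = n_new
            state._append_cohorts(
                np.array(rows, dtype=np.int64),
                np.full(len(rows), _IMAGO, dtype=np.int64),
                np.array(counts, dtype=np.int64),
            )

    # prune empty cohorts, track the yearly imago maximum
    keep = state.count > 0
    if not keep.all():
        state.cellrow = state.cellrow[keep]
        state.stage = state.stage[keep]
        state.count = state.count[keep]
        state.dev = state.dev[keep]
        state.age = state.age[keep]
    imago_mask = state.stage == _IMAGO
    if imago_mask.any():
        dens = (
            np.bincount(
                state.cellrow[imago_mask],
                weights=state.count[imago_mask],
                minlength=n_rows,
            )
            / area
        )
        if len(state.year_max_imago) < n_rows:
            state.year_max_imago = np.append(
                state.year_max_imago,
                np.zeros(n_rows - len(state.year_max_imago)),
            )
        np.maximum(state.year_max_imago, dens, out=state.year_max_imago)

    state.day += 1
    if len(state.count) == 0:
        state.extinct = True

    # (7) end-of-year bookkeeping
    if day_of_year == DAYS_PER_YEAR or state.extinct:
        year_index = (state.day - 1) // DAYS_PER_YEAR
        if day_of_year == DAYS_PER_YEAR or not any(
            m.year == year_index + 1 for m in state.yearly
        ):
            per_row = np.bincount(
                state.cellrow, weights=state.count, minlength=len(state.row_cells)
            )
            occupied_density = {
                state.row_cells[r]: per_row[r] / area
                for r in np.flatnonzero(per_row)
            }
            ymax = {
                state.row_cells[r]: state.year_max_imago[r]
                for r in range(len(state.year_max_imago))
            }
            landscape = config.landscape
            snap = yearly_snapshot(
                year=year_index + 1,
                source_xy=landscape.center_xy(state.source_cell),
                occupied=occupied_density,
                cell_xy=landscape.center_xy,
                year_max_imago=ymax,
                direct_ldd_cells=state.direct_ldd_cells,
                cell_area=area,
                threshold=config.established_threshold,
            )
            state.yearly.append(snap)
        if day_of_year == DAYS_PER_YEAR:
            state.year_max_imago[:] = 0.0


def run(config: SimulationConfig, replicate: int = 0) -> RunResult:
    """Execute one replicate to the horizon or global extinction."""
    state = initialize_run(config, replicate)
    horizon = config.scheduled_steps
    while state.day < horizon and not state.extinct:
        step_day(state)
    return RunResult(
        replicate=replicate,
        yearly=state.yearly,
        steps_executed=state.day,
        scheduled_steps=horizon,
        extinct=state.extinct,
        state=state,
    )


def run_replicates(config: SimulationConfig) -> list[RunResult]:
    """Run all replicates with independent derived seeds."""
    return [run(config, replicate=r) for r in range(config.replicates)]


def replicate_summary(results: list[RunResult]) -> pd.DataFrame:
    """Per-year mean and SD of the evaluation parameters across replicates.

    Years after an early extinction contribute zeros, so every replicate
    covers the same year axis.
    """
    n_years = results[0].scheduled_steps // DAYS_PER_YEAR
    cols = [
        "occupied_cells",
        "established_cells",
        "max_dispersal_distance_m",
        "max_established_distance_m",
        "population_size",
        "population_density",
    ]
    per_rep = np.zeros((len(results), n_years, len(cols)))
    for r, res in enumerate(results):
        frame = res.metrics_frame().set_index("year")
        for y in range(1, n_years + 1):
            if y in frame.index:
                per_rep[r, y - 1] = frame.loc[y, cols].to_numpy(dtype=float)
    records = []
    for y in range(n_years):
        rec = {"year": y + 1}
        for ci, col in enumerate(cols):
            rec[f"{col}_mean"] = per_rep[:, y, ci].mean()
            rec[f"{col}_sd"] = per_rep[:, y, ci].std(ddof=1) if len(results) > 1 else 0.0
        records.append(rec)
    return pd.DataFrame(records)


def write_run_outputs(results: list[RunResult], out_dir, config: SimulationConfig) -> None:
    """Write per-replicate metrics CSVs, a summary CSV and run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for res in results:
        res.metrics_frame().to_csv(out / f"metrics_rep{res.replicate}.csv", index=False)
    replicate_summary(results).to_csv(out / "metrics_summary.csv", index=False)
    meta = {
        "master_seed": config.master_seed,
        "replicates": config.replicates,
        "years": config.years,
        "scheduled_steps": config.scheduled_steps,
        "dispersal_enabled": config.dispersal_enabled,
        "schedule": config.schedule.acronym,
        "source_climate_cell": config.source_climate_cell,
        "process_ordering": [
            "drivers",
            "mowing",
            "demography",
            "dispersal",
            "activation",
        ],
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
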