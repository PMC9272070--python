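"""Nested habitat/climate lattices and their geometric queries.

A :class:`Landscape` couples a fine lattice of 250 m habitat cells (each
flagged grassland or not) with a coarse lattice of 12 km climate cells.
Every grassland cell is assigned the (up to) four climate cells whose
centres enclose it, keyed by secondary cardinal direction (NE, SE, SW,
NW), together with bilinear interpolation weights.  The module also
provides the geometric queries the dispersal process needs: grassland
cover within a radius, the in-radius neighbourhood of a source cell, and
the selection of long-distance dispersal (LDD) targets in the eight
cardinal/secondary-cardinal directions.

Conventions
-----------
* Lattice indices are 0-based; cell centres sit at ``(i + 0.5) * width``.
* Cell ids enumerate the full rectangular lattice row-major
  (``id = iy * nx + ix``), so non-grassland cells have ids too.
* ``y`` grows northward, ``x`` eastward; distances are planar Euclidean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import SIZE_CLIM, SIZE_HAB

__all__ = [
    "ClimateGridSpec",
    "Landscape",
    "Neighborhood",
    "bilinear_weights",
    "build_landscape",
    "build_neighborhood",
    "grassland_cover",
    "select_ldd_targets",
    "read_landscape_csv",
    "write_landscape_csv",
    "write_landscape_geojson",
    "write_weight_table",
]

#: Secondary cardinal directions used to key the enclosing climate cells.
SEC_DIRECTIONS = ("NE", "SE", "SW", "NW")

#: All eight dispersal search directions with their azimuth (degrees,
#: mathematical convention: E = 0, counter-clockwise positive).
DIRECTIONS = {
    "E": 0.0,
    "NE": 45.0,
    "N": 90.0,
    "NW": 135.0,
    "W": 180.0,
    "SW": 225.0,
    "S": 270.0,
    "SE": 315.0,
}

SECTOR_HALF_WIDTH_DEG = 22.5


@dataclass(frozen=True)
class ClimateGridSpec:
    """Geometry of the coarse climate lattice.

    ``origin`` is the south-west corner of climate cell (0, 0) in metres.
    """

    nx: int
    ny: int
    size: float = SIZE_CLIM
    origin: tuple[float, float] = (0.0, 0.0)

    def center(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            self.origin[0] + (ix + 0.5) * self.size,
            self.origin[1] + (iy + 0.5) * self.size,
        )

    def cell_id(self, ix: int, iy: int) -> int:
        return iy * self.nx + ix

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny


@dataclass
class Neighborhood:
    """Dispersal neighbourhood of one source cell.

    ``in_radius`` holds ``(target_id, distance_m)`` for every grassland
    cell whose centre lies within ``(0, rad_disp]`` of the source centre.
    ``ldd`` holds ``(target_id, distance_m, direction)`` for directions
    whose angular sector contains no in-radius grassland.
    """

    source: int
    in_radius: list[tuple[int, float]] = field(default_factory=list)
    ldd: list[tuple[int, float, str]] = field(default_factory=list)


class Landscape:
    """Fine grassland lattice nested in a coarse climate lattice."""

    def __init__(
        self,
        is_grassland: np.ndarray,
        climate_spec: ClimateGridSpec,
        size_hab: float = SIZE_HAB,
    ):
        # is_grassland indexed [iy, ix]
        self.is_grassland = np.asarray(is_grassland, dtype=bool)
        self.ny, self.nx = self.is_grassland.shape
        self.size_hab = float(size_hab)
        self.climate_spec = climate_spec

        flat = self.is_grassland.ravel()
        self.grassland_ids = np.flatnonzero(flat)

        ix = np.arange(self.nx * self.ny) % self.nx
        iy = np.arange(self.nx * self.ny) // self.nx
        self._centers_x = (ix + 0.5) * self.size_hab
        self._centers_y = (iy + 0.5) * self.size_hab

        # filled by build_landscape
        self.weights: dict[int, list[tuple[int, str, float]]] = {}
        self._weight_matrix: np.ndarray | None = None
        self._row_of: dict[int, int] = {
            int(g): r for r, g in enumerate(self.grassland_ids)
        }

    # -- basic geometry -------------------------------------------------

    def center_xy(self, cell_id: int) -> tuple[float, float]:
        return float(self._centers_x[cell_id]), float(self._centers_y[cell_id])

    def grid_xy(self, cell_id: int) -> tuple[int, int]:
        return cell_id % self.nx, cell_id // self.nx

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def grassland_centers(self) -> np.ndarray:
        """(n_grassland, 2) array of grassland cell centres."""
        g = self.grassland_ids
        return np.column_stack([self._centers_x[g], self._centers_y[g]])

    def weight_row(self, cell_id: int) -> int:
        return self._row_of[int(cell_id)]

    @property
    def weight_matrix(self) -> np.ndarray:
        """Dense (n_grassland, n_climate) bilinear weight matrix."""
        if self._weight_matrix is None:
            W = np.zeros((len(self.grassland_ids), self.climate_spec.n_cells))
            for gid, entries in self.weights.items():
                r = self._row_of[gid]
                for cid, _direction, w in entries:
                    W[r, cid] += w
            self._weight_matrix = W
        return self._weight_matrix


def bilinear_weights(
    point_xy: tuple[float, float],
    centers: dict[str, tuple[float, float]],
    size_clim: float = SIZE_CLIM,
) -> dict[str, float]:
    """Bilinear weights of the enclosing climate-cell centres at a point.

    Each available centre receives the standard bilinear weight

    ``w = max(0, 1 - |dx|/size) * max(0, 1 - |dy|/size)``,

    renormalised so the weights over the *available* centres sum to 1.
    Centres closer to the point receive strictly larger weights, and at a
    centre the weight collapses to 1.  If the point lies outside the
    rectangle spanned by the available centres in both axes (all raw
    weights zero), the nearest centre gets weight 1.
    """
    if not centers:
        raise ValueError("no climate-cell centers supplied")
    raw: dict[str, float] = {}
    px, py = point_xy
    for direction, (cx, cy) in centers.items():
        wx = max(0.0, 1.0 - abs(px - cx) / size_clim)
        wy = max(0.0, 1.0 - abs(py - cy) / size_clim)
        raw[direction] = wx * wy
    total = sum(raw.values())
    if total <= 0.0:
        # fallback: nearest available centre takes all the weight
        nearest = min(
            centers,
            key=lambda d: math.hypot(px - centers[d][0], py - centers[d][1]),
        )
        return {d: (1.0 if d == nearest else 0.0) for d in centers}
    return {d: w / total for d, w in raw.items()}


def build_landscape(
    habitat_grid: np.ndarray,
    climate_spec: ClimateGridSpec,
    size_hab: float = SIZE_HAB,
) -> Landscape:
    """Assemble a :class:`Landscape` and its climate-cell mapping.

    Every grassland cell is mapped to the up-to-4 climate cells whose
    centres enclose it (fewer at lattice boundaries, where weights are
    renormalised over the available cells).  A grassland cell lying
    outside the climate lattice entirely is a hard error.
    """
    ls = Landscape(habitat_grid, climate_spec, size_hab=size_hab)
    spec = climate_spec
    ox, oy = spec.origin
    for gid in ls.grassland_ids:
        gid = int(gid)
        px, py = ls.center_xy(gid)
        # reject cells outside climate coverage (union of cell squares)
        if not (
            ox <= px <= ox + spec.nx * spec.size
            and oy <= py <= oy + spec.ny * spec.size
        ):
            raise ValueError(
                f"grassland cell {gid} at ({px:.0f}, {py:.0f}) m lies "
                "outside the climate lattice"
            )
        # fractional index of the point in centre coordinates
        u = (px - ox) / spec.size - 0.5
        v = (py - oy) / spec.size - 0.5
        i0 = math.floor(u)
        j0 = math.floor(v)
        # enclosing centre quadruple, keyed by secondary direction
        quad = {"SW": (i0, j0), "SE": (i0 + 1, j0), "NW": (i0, j0 + 1), "NE": (i0 + 1, j0 + 1)}
        centers: dict[str, tuple[float, float]] = {}
        ids: dict[str, int] = {}
        for direction, (ci, cj) in quad.items():
            if 0 <= ci < spec.nx and 0 <= cj < spec.ny:
                centers[direction] = spec.center(ci, cj)
                ids[direction] = spec.cell_id(ci, cj)
        if not centers:
            raise ValueError(
                f"grassland cell {gid} has no enclosing climate-cell centre"
            )
        ws = bilinear_weights((px, py), centers, size_clim=spec.size)
        ls.weights[gid] = [
            (ids[d], d, w) for d, w in ws.items()
        ]
    return ls


def grassland_cover(
    landscape: Landscape, center_xy: tuple[float, float], radius: float
) -> float:
    """Fraction of lattice cells within ``radius`` that are grassland.

    The denominator counts *all* lattice cells whose centre lies within
    the radius, grassland or not, mirroring a percental-cover map.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    px, py = center_xy
    d2 = (landscape._centers_x - px) ** 2 + (landscape._centers_y - py) ** 2
    inside = d2 <= radius * radius
    n_total = int(inside.sum())
    if n_total == 0:
        raise ValueError("no lattice cells within radius of the given centre")
    n_grass = int((inside & landscape.is_grassland.ravel()).sum())
    return n_grass / n_total


def build_neighborhood(
    landscape: Landscape, source: int, rad_disp: float
) -> Neighborhood:
    """In-radius dispersal targets of a grassland source cell.

    Targets are all grassland cells with centre distance in
    ``(0, rad_disp]``; LDD targets are filled in by
    :func:`select_ldd_targets`.
    """
    if not landscape.is_grassland.ravel()[source]:
        raise ValueError(f"source cell {source} is not grassland")
    px, py = landscape.center_xy(source)
    g = landscape.grassland_ids
    dx = landscape._centers_x[g] - px
    dy = landscape._centers_y[g] - py
    dist = np.hypot(dx, dy)
    mask = (dist > 0) & (dist <= rad_disp)
    nb = Neighborhood(source=source)
    order = np.argsort(dist[mask], kind="stable")
    ids = g[mask][order]
    ds = dist[mask][order]
    nb.in_radius = [(int(i), float(d)) for i, d in zip(ids, ds)]
    nb.ldd = select_ldd_targets(landscape, source, rad_disp)
    return nb


def _sector_mask(dx: np.ndarray, dy: np.ndarray, azimuth: float) -> np.ndarray:
    """Cells strictly inside the 45° sector centred on ``azimuth``.

    Both boundary rays are open: cells lying exactly on a sector
    boundary are excluded from the search in either adjacent direction.
    """
    ang = np.degrees(np.arctan2(dy, dx))
    diff = (ang - azimuth + 180.0) % 360.0 - 180.0
    return np.abs(diff) < SECTOR_HALF_WIDTH_DEG


def select_ldd_targets(
    landscape: Landscape, source: int, rad_disp: float
) -> list[tuple[int, float, str]]:
    """Long-distance dispersal targets of a source cell.

    For each of the eight cardinal/secondary-cardinal directions: if the
    45° angular sector centred on that direction contains no grassland
    cell within ``rad_disp``, the nearest grassland cell beyond the
    radius inside the sector (if any) is selected.  Distance ties break
    on the lowest cell id.
    """
    px, py = landscape.center_xy(source)
    g = landscape.grassland_ids
    dx = landscape._centers_x[g] - px
    dy = landscape._centers_y[g] - py
    dist = np.hypot(dx, dy)
    nonself = dist > 0
    targets: list[tuple[int, float, str]] = []
    for direction, azimuth in DIRECTIONS.items():
        in_sector = _sector_mask(dx, dy, azimuth) & nonself
        if np.any(in_sector & (dist <= rad_disp)):
            continue  # nearby grassland takes priority; no LDD here
        beyond = in_sector & (dist > rad_disp)
        if not np.any(beyond):
            continue
        cand_ids = g[beyond]
        cand_dist = dist[beyond]
        dmin = cand_dist.min()
        tied = cand_ids[cand_dist == dmin]
        best = int(tied.min())
        targets.append((best, float(dmin), direction))
    return targets


# -- input/output ------------------------------------------------------


def write_landscape_csv(landscape: Landscape, path) -> None:
    """Write the habitat lattice as CSV.

    Columns: ``cell_id, grid_x, grid_y, is_grassland, climate_cell_id``
    where the climate id is the dominant (largest-weight) enclosing
    climate cell for grassland cells and empty otherwise.
    """
    n = landscape.n_cells
    clim = np.full(n, -1, dtype=int)
    for gid, entries in landscape.weights.items():
        clim[gid] = max(entries, key=lambda e: e[2])[0]
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "grid_x": np.arange(n) % landscape.nx,
            "grid_y": np.arange(n) // landscape.nx,
            "is_grassland": landscape.is_grassland.ravel().astype(int),
            "climate_cell_id": clim,
        }
    )
    df.to_csv(path, index=False)


def read_landscape_csv(path, climate_spec: ClimateGridSpec) -> Landscape:
    """Read a habitat lattice CSV written by :func:`write_landscape_csv`."""
    df = pd.read_csv(path)
    required = {"cell_id", "grid_x", "grid_y", "is_grassland"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landscape CSV missing columns: {sorted(missing)}")
    nx = int(df["grid_x"].max()) + 1
    ny = int(df["grid_y"].max()) + 1
    if len(df) != nx * ny:
        raise ValueError("landscape CSV does not describe a full rectangle")
    grid = np.zeros((ny, nx), dtype=bool)
    grid[df["grid_y"].to_numpy(), df["grid_x"].to_numpy()] = (
        df["is_grassland"].to_numpy().astype(bool)
    )
    return build_landscape(grid, climate_spec)


def write_landscape_geojson(landscape: Landscape, path) -> None:
    """Write grassland cells as a GeoJSON FeatureCollection of squares."""
    h = landscape.size_hab / 2.0
    features = []
    for gid in landscape.grassland_ids:
        gid = int(gid)
        cx, cy = landscape.center_xy(gid)
        ring = [
            [cx - h, cy - h],
            [cx + h, cy - h],
            [cx + h, cy + h],
            [cx - h, cy + h],
            [cx - h, cy - h],
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"cell_id": gid, "is_grassland": True},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(collection, fh)


def write_weight_table(landscape: Landscape, path) -> None:
    """Export the bilinear weight mapping as CSV for audit.

    Columns: ``grassland_id, climate_id, direction, weight``.
    """
    rows = []
    for gid in sorted(landscape.weights):
        for cid, direction, w in landscape.weights[gid]:
            rows.append((gid, cid, direction, w))
    pd.DataFrame(
        rows, columns=["grassland_id", "climate_id", "direction", "weight"]
    ).to_csv(path, index=False)
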