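"""Analysis grids and fine-to-coarse aggregation.

Two grid families are supported: a long-lat grid (cells in degrees, areas
shrinking toward the pole) and an equal-area grid laid out on the
Mollweide plane (cells in km, constant area).  Aggregation assigns each
fine cell to the coarse cell containing its center and produces the
per-cell table the models are fitted on: land-masked predictor means,
land fraction, range coverage, presence, area and the three regression
weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import (
    ProjectionParams,
    longlat_cell_area,
    mollweide_forward,
)
from .world import PREDICTOR_NAMES, FineWorld

logger = logging.getLogger(__name__)

LONGLAT = "longlat"
EQUALAREA = "equalarea"

#: fixed column order of a cell table on disk
CELL_COLUMNS = [
    "cell_id",
    "ix",
    "iy",
    "x_center",
    "y_center",
    "center_lat",
    "area_km2",
    "land_fraction",
    "coverage_fraction",
    "presence",
    *PREDICTOR_NAMES,
    "weight_area",
    "weight_land",
    "weight_combined",
]


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """A regular analysis grid in its native plane.

    Native units are degrees for ``longlat`` and Mollweide-plane km for
    ``equalarea``.  Cells are identified by their lower-left corner and
    intervals are half-open [low, high); indexing is row-major from the
    lower-left.
    """

    projection: str
    cell_size: float
    origin: tuple[float, float]
    nx: int
    ny: int

    def __post_init__(self):
        if self.projection not in (LONGLAT, EQUALAREA):
            raise GridError(f"unknown projection {self.projection!r}")
        if self.cell_size <= 0 or self.nx < 1 or self.ny < 1:
            raise GridError("degenerate grid")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, x0 + self.nx * self.cell_size, y0, y0 + self.ny * self.cell_size)

    def cell_indices(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Native coordinates -> (ix, iy); points outside get index -1."""
        x0, y0 = self.origin
        ix = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        bad = (ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)
        ix = np.where(bad, -1, ix)
        iy = np.where(bad, -1, iy)
        return ix, iy

    def centers(self, ix, iy) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        return (
            x0 + (np.asarray(ix) + 0.5) * self.cell_size,
            y0 + (np.asarray(iy) + 0.5) * self.cell_size,
        )

    def to_dict(self) -> dict:
        return {
            "projection": self.projection,
            "cell_size": self.cell_size,
            "origin": list(self.origin),
            "nx": self.nx,
            "ny": self.ny,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            projection=d["projection"],
            cell_size=float(d["cell_size"]),
            origin=tuple(d["origin"]),
            nx=int(d["nx"]),
            ny=int(d["ny"]),
        )


def build_grid(projection: str, cell_size: float, extent) -> GridSpec:
    """Lay out a grid covering ``extent`` = (xmin, xmax, ymin, ymax) in
    native units, snapped outward to whole cells anchored at (0, 0).

    The equal-area grid is anchored at the Mollweide origin, so cell
    boundaries are stable regardless of the study window.
    """
    xmin, xmax, ymin, ymax = (float(v) for v in extent)
    if xmax <= xmin or ymax <= ymin:
        raise GridError("study extent is empty")
    eps = 1e-9
    i0 = np.floor(xmin / cell_size + eps)
    i1 = np.ceil(xmax / cell_size - eps)
    j0 = np.floor(ymin / cell_size + eps)
    j1 = np.ceil(ymax / cell_size - eps)
    y_lo, y_hi = j0 * cell_size, j1 * cell_size
    if projection == LONGLAT and (y_hi > 90 + eps or y_lo < -90 - eps):
        # rows must not cross a pole; re-anchor the rows at the pole
        anchor = 90.0 if y_hi > 90 else -90.0
        if anchor == 90.0:
            ny = int(np.ceil((anchor - ymin) / cell_size - eps))
            y_lo, y_hi = anchor - ny * cell_size, anchor
        else:
            ny = int(np.ceil((ymax - anchor) / cell_size - eps))
            y_lo, y_hi = anchor, anchor + ny * cell_size
        if y_lo < -90 - eps or y_hi > 90 + eps:
            raise GridError("cell size does not fit inside the latitude span")
    snapped = (i0 * cell_size, i1 * cell_size, y_lo, y_hi)
    if not np.allclose(snapped, (xmin, xmax, ymin, ymax)):
        logger.info("study extent %s snapped outward to %s", extent, snapped)
    return GridSpec(
        projection=projection,
        cell_size=cell_size,
        origin=(snapped[0], snapped[2]),
        nx=int(i1 - i0),
        ny=int(round((y_hi - y_lo) / cell_size)),
    )


def equalarea_extent(
    lon_extent, lat_extent, params: ProjectionParams, n_samples: int = 721
) -> tuple[float, float, float, float]:
    """Mollweide-plane bounding box of a lon-lat rectangle (boundary sampled)."""
    lons = np.linspace(lon_extent[0], lon_extent[1], n_samples)
    lats = np.linspace(lat_extent[0], lat_extent[1], n_samples)
    # widest parallel dominates x; sample all four edges to be safe
    edge_lon = np.concatenate([lons, lons, np.full(n_samples, lon_extent[0]), np.full(n_samples, lon_extent[1])])
    edge_lat = np.concatenate([np.full(n_samples, lat_extent[0]), np.full(n_samples, lat_extent[1]), lats, lats])
    # avoid the exact antimeridian wrapping to -180
    edge_lon = np.clip(edge_lon, -180.0, 180.0 - 1e-9)
    x, y = mollweide_forward(edge_lon, edge_lat, params)
    return (x.min(), x.max(), y.min(), y.max())


def grid_for_world(world_spec, projection: str, cell_size: float, params: ProjectionParams | None = None) -> GridSpec:
    """Convenience: grid of the requested family covering a world's band."""
    if params is None:
        params = ProjectionParams(earth_radius=world_spec.earth_radius)
    if projection == LONGLAT:
        extent = (*world_spec.lon_extent, *world_spec.lat_extent)
    else:
        extent = equalarea_extent(world_spec.lon_extent, world_spec.lat_extent, params)
    return build_grid(projection, cell_size, extent)


class GridAggregator:
    """Precomputed fine-cell -> coarse-cell assignment for one world/grid
    pair, so several species can be aggregated without re-projecting.

    Each fine cell is represented as an axis-aligned, area-preserving
    rectangle in the grid's native plane and its area is split across the
    (at most four) coarse cells that rectangle overlaps.  For the long-lat
    grid the rectangle is the fine cell itself, so nested resolutions
    aggregate exactly; for the equal-area grid the rectangle has the true
    Mollweide band height of the fine cell's latitude row and a width
    chosen to preserve its spherical area, making the split second-order
    accurate in the resolution ratio.
    """

    def __init__(self, world: FineWorld, grid: GridSpec, params: ProjectionParams | None = None):
        spec = world.spec
        if params is None:
            params = ProjectionParams(earth_radius=spec.earth_radius)
        fine_native = (
            spec.fine_resolution
            if grid.projection == LONGLAT
            else spec.fine_resolution * 112.0  # upper bound on ground size, km
        )
        if fine_native >= grid.cell_size:
            raise GridError("fine resolution must be strictly finer than the grid cell size")

        self.world = world
        self.grid = grid
        self.params = params

        lat2d = np.broadcast_to(spec.lat_centers[:, None], spec.shape)
        lon2d = np.broadcast_to(spec.lon_centers[None, :], spec.shape)
        self._fine_area = spec.cell_areas().ravel()
        self._fine_lat = lat2d.ravel()
        half = spec.fine_resolution / 2.0

        if grid.projection == LONGLAT:
            xlo = (lon2d - half).ravel()
            xhi = (lon2d + half).ravel()
            ylo = (lat2d - half).ravel()
            yhi = (lat2d + half).ravel()
        else:
            # band heights from the exact y of the latitude edges
            lat_edges = np.concatenate(
                [spec.lat_centers - half, [spec.lat_centers[-1] + half]]
            )
            _, y_edges = mollweide_forward(np.zeros_like(lat_edges), lat_edges, params)
            y_lo_row = y_edges[:-1]
            y_hi_row = y_edges[1:]
            ylo = np.broadcast_to(y_lo_row[:, None], spec.shape).ravel()
            yhi = np.broadcast_to(y_hi_row[:, None], spec.shape).ravel()
            xc, _ = mollweide_forward(lon2d.ravel(), lat2d.ravel(), params)
            width = self._fine_area / (yhi - ylo)
            xlo = xc - width / 2.0
            xhi = xc + width / 2.0

        self._build_split(xlo, xhi, ylo, yhi)

    def _build_split(self, xlo, xhi, ylo, yhi):
        grid = self.grid
        cs = grid.cell_size
        x0, y0 = grid.origin

        def axis_split(lo, hi, origin):
            glo = (lo - origin) / cs
            ghi = (hi - origin) / cs
            i0 = np.floor(glo).astype(np.int64)
            span = ghi - glo
            with np.errstate(invalid="ignore", divide="ignore"):
                f0 = np.where(span > 0, np.clip((i0 + 1 - glo) / np.where(span == 0, 1.0, span), 0.0, 1.0), 1.0)
            return i0, f0

        ix0, fx0 = axis_split(xlo, xhi, x0)
        iy0, fy0 = axis_split(ylo, yhi, y0)

        self._parts = []
        for dx, dy in ((0, 0), (1, 0), (0, 1), (1, 1)):
            ix = ix0 + dx
            iy = iy0 + dy
            fx = fx0 if dx == 0 else 1.0 - fx0
            fy = fy0 if dy == 0 else 1.0 - fy0
            frac = fx * fy
            valid = (
                (frac > 0)
                & (ix >= 0)
                & (ix < grid.nx)
                & (iy >= 0)
                & (iy < grid.ny)
            )
            self._parts.append(
                (np.where(valid, iy * grid.nx + ix, 0), np.where(valid, frac, 0.0))
            )
        self._n_flat = grid.n_cells

    def _sum(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros(self._n_flat)
        for flat, frac in self._parts:
            out += np.bincount(flat, weights=values * frac, minlength=self._n_flat)
        return out

    def aggregate(self, presence_threshold: float = 0.10) -> pd.DataFrame:
        """Build the cell table (see :data:`CELL_COLUMNS`) for the world's
        current species.  Cells receiving no fine cells are dropped."""
        world, grid = self.world, self.grid
        land = world.land_mask.ravel().astype(float)
        fa = self._fine_area

        total_area = self._sum(fa)
        land_area = self._sum(fa * land)
        occupied = total_area > 0
        flat_ids = np.flatnonzero(occupied)

        iy, ix = np.divmod(flat_ids, grid.nx)
        xc, yc = grid.centers(ix, iy)
        if grid.projection == LONGLAT:
            south = grid.origin[1] + iy * grid.cell_size
            area = longlat_cell_area(
                south, south + grid.cell_size, grid.cell_size, world.spec.earth_radius
            )
        else:
            area = np.full(flat_ids.shape, grid.cell_size**2)

        mean_lat = self._sum(fa * self._fine_lat)[occupied] / total_area[occupied]
        # fractions of the nominal cell area; with the split assignment the
        # assigned fine area matches it closely, so the clip is a no-op
        # except for float jitter
        land_fraction = np.clip(land_area[occupied] / area, 0.0, 1.0)

        if world.presence is not None:
            pres = world.presence.ravel().astype(float)
            cover = self._sum(fa * pres)[occupied]
            coverage_fraction = np.clip(cover / area, 0.0, 1.0)
        else:
            coverage_fraction = np.zeros(flat_ids.shape)

        table = pd.DataFrame(
            {
                "cell_id": flat_ids,
                "ix": ix,
                "iy": iy,
                "x_center": xc,
                "y_center": yc,
                "center_lat": mean_lat,
                "area_km2": area,
                "land_fraction": land_fraction,
                "coverage_fraction": coverage_fraction,
            }
        )
        table["presence"] = presence_from_coverage(coverage_fraction, presence_threshold)

        la = land_area[occupied]
        for name in PREDICTOR_NAMES:
            vals = np.nan_to_num(world.predictors[name].ravel(), nan=0.0)
            s = self._sum(fa * land * vals)[occupied]
            with np.errstate(invalid="ignore", divide="ignore"):
                table[name] = np.where(la > 0, s / np.where(la == 0, 1.0, la), np.nan)

        return compute_weights(table)


def aggregate_to_grid(
    world: FineWorld,
    grid: GridSpec,
    params: ProjectionParams | None = None,
    presence_threshold: float = 0.10,
) -> pd.DataFrame:
    """One-shot aggregation of a world onto a grid."""
    table = GridAggregator(world, grid, params).aggregate(presence_threshold)
    if len(table) == 0:
        raise GridError("grid does not intersect the world")
    return table


def presence_from_coverage(coverage_fraction, threshold: float = 0.10):
    """Presence iff coverage is *strictly* greater than the threshold."""
    cov = np.asarray(coverage_fraction, dtype=float)
    if np.any((cov < 0) | (cov > 1)):
        raise GridError("coverage_fraction outside [0, 1]")
    return (cov > threshold).astype(int)


def compute_weights(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the three regression weights.

    weight_area = cell area / max cell area (1 everywhere on an equal-area
    grid); weight_land = land fraction; weight_combined = their product.
    """
    max_area = table["area_km2"].max()
    if not max_area > 0:
        raise GridError("degenerate grid: max cell area is 0")
    table = table.copy()
    table["weight_area"] = table["area_km2"] / max_area
    table["weight_land"] = table["land_fraction"]
    table["weight_combined"] = table["weight_area"] * table["weight_land"]
    return table[CELL_COLUMNS]


def land_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Cells entering model fitting: land_fraction > 0."""
    return table[table["land_fraction"] > 0].reset_index(drop=True)


def write_cell_table(table: pd.DataFrame, path, grid: GridSpec | None = None):
    """CSV with the fixed column order; grid metadata in a JSON sidecar."""
    path = Path(path)
    table[CELL_COLUMNS].to_csv(path, index=False)
    if grid is not None:
        path.with_suffix(".grid.json").write_text(json.dumps(grid.to_dict(), indent=2))


def read_cell_table(path) -> tuple[pd.DataFrame, GridSpec | None]:
    path = Path(path)
    table = pd.read_csv(path)
    sidecar = path.with_suffix(".grid.json")
    grid = GridSpec.from_dict(json.loads(sidecar.read_text())) if sidecar.exists() else None
    return table, grid
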