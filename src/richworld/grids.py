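"""Equal-area grids and gridded fields.

The analysis grid is a Lambert cylindrical equal-area grid (standard
parallel at the equator): longitude maps to ``x = R * lambda`` and latitude
to ``y = R * sin(phi)``, so cells of constant ``dx * dy`` have constant
area on the sphere.  Cell size defaults to 50 km.

Fields live on the grid either as a single 2-D layer (:class:`RasterLayer`)
or as a monthly stack (:class:`RasterTimeSeries`).  Missing / out-of-domain
cells are NaN; the grid itself carries a per-cell domain mask
(land, ocean or excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: domain mask codes
EXCLUDED, LAND, OCEAN = 0, 1, 2
_DOMAIN_CODES = {"excluded": EXCLUDED, "land": LAND, "ocean": OCEAN}


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments violating its contract."""


class GenerationError(RuntimeError):
    """Raised when a stochastic generator cannot satisfy its contract."""


@dataclass
class GridSpec:
    """A cylindrical equal-area grid.

    Attributes
    ----------
    n_rows, n_cols : int
        Grid shape; row 0 is the southernmost row.
    cell_km : float
        Side of a cell on the equal-area plane (km); cell area is
        ``cell_km ** 2`` everywhere.
    lat, lon : ndarray
        Centroid latitudes (n_rows,) and longitudes (n_cols,), degrees.
    mask : ndarray of int8
        Per-cell domain code: 0 excluded, 1 land, 2 ocean.
    """

    n_rows: int
    n_cols: int
    cell_km: float
    lat: np.ndarray
    lon: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.mask is None:
            self.mask = np.full((self.n_rows, self.n_cols), LAND, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.lat.shape != (self.n_rows,) or self.lon.shape != (self.n_cols,):
            raise InvalidInputError("centroid arrays do not match grid shape")
        if self.mask.shape != self.shape:
            raise InvalidInputError("mask does not match grid shape")
        if np.any(np.abs(self.lat) > 90.0):
            raise InvalidInputError("centroid latitudes must lie in [-90, 90]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lat_grid(self) -> np.ndarray:
        """Centroid latitude of every cell, shape (n_rows, n_cols)."""
        return np.broadcast_to(self.lat[:, None], self.shape)

    def lon_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lon[None, :], self.shape)

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells).reshape(self.shape)

    def domain_mask(self, domain: str | None = None) -> np.ndarray:
        """Boolean mask of cells in ``domain`` ('land'|'ocean'|None=any non-excluded)."""
        if domain is None or domain == "any":
            return self.mask != EXCLUDED
        try:
            code = _DOMAIN_CODES[domain]
        except KeyError:
            raise InvalidInputError(f"unknown domain {domain!r}") from None
        return self.mask == code

    def plane_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell centroid (x, y) on the equal-area plane in km, shape (n_rows, n_cols).

        Distances between cells on this plane are the distances used by the
        semivariogram; by construction adjacent cells are ``cell_km`` apart.
        """
        y = np.arange(self.n_rows, dtype=float)[:, None] * self.cell_km
        x = np.arange(self.n_cols, dtype=float)[None, :] * self.cell_km
        return np.broadcast_to(x, self.shape), np.broadcast_to(y, self.shape)

    def cell_bounds(self, row: np.ndarray, col: np.ndarray):
        """(lat_lo, lat_hi, lon_lo, lon_hi) of the given cells, degrees."""
        # invert the equal-area construction used by make_grid
        sin_edges = self._sin_edges
        lon_edges = self._lon_edges
        return (
            np.degrees(np.arcsin(sin_edges[row])),
            np.degrees(np.arcsin(sin_edges[row + 1])),
            lon_edges[col],
            lon_edges[col + 1],
        )

    # populated by make_grid; fall back to local reconstruction for
    # hand-built grids
    _sin_edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _lon_edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class RasterLayer:
    """A single 2-D field on a :class:`GridSpec` (NaN = missing)."""

    grid: GridSpec
    values: np.ndarray
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InvalidInputError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, values, name if name is not None else self.name)

    def to_dataframe(self) -> pd.DataFrame:
        g = self.grid
        return pd.DataFrame(
            {
                "cell_id": g.cell_ids().ravel(),
                "lon": g.lon_grid().ravel(),
                "lat": g.lat_grid().ravel(),
                self.name: self.values.ravel(),
            }
        )

    def to_xarray(self):
        import xarray as xr

        return xr.DataArray(
            self.values,
            dims=("lat", "lon"),
            coords={"lat": self.grid.lat, "lon": self.grid.lon},
            name=self.name,
        )


@dataclass
class RasterTimeSeries:
    """A monthly stack on a grid: values shape (n_months, n_rows, n_cols)."""

    grid: GridSpec
    values: np.ndarray
    name: str = "series"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise InvalidInputError(
                f"series {self.name!r}: values shape {self.values.shape} "
                f"incompatible with grid {self.grid.shape}"
            )

    @property
    def n_months(self) -> int:
        return self.values.shape[0]

    def cell_series(self, row: int, col: int) -> np.ndarray:
        return self.values[:, row, col]

    def temporal_mean(self) -> RasterLayer:
        return RasterLayer(self.grid, self.values.mean(axis=0), f"{self.name}_mean")

    def to_xarray(self):
        import xarray as xr

        return xr.DataArray(
            self.values,
            dims=("month", "lat", "lon"),
            coords={
                "month": np.arange(self.n_months),
                "lat": self.grid.lat,
                "lon": self.grid.lon,
            },
            name=self.name,
        )


def make_grid(
    extent: tuple[float, float, float, float] = (-90.0, 90.0, -180.0, 180.0),
    cell_km: float = 50.0,
    radius_km: float = EARTH_RADIUS_KM,
) -> GridSpec:
    """Build a cylindrical equal-area grid over ``extent``.

    Parameters
    ----------
    extent : (lat_min, lat_max, lon_min, lon_max) in degrees.
    cell_km : cell side on the equal-area plane; every cell covers
        ``cell_km**2`` of surface area.

    The number of rows/columns is the rounded number of ``cell_km`` steps the
    extent spans on the plane (at least 1 each); centroids sit at cell
    midpoints, so for the full globe centroid latitudes approach but never
    equal +/-90.
    """
    lat_min, lat_max, lon_min, lon_max = map(float, extent)
    if not (lat_min < lat_max and lon_min < lon_max):
        raise InvalidInputError(f"degenerate extent {extent}")
    if not (-90.0 <= lat_min and lat_max <= 90.0):
        raise InvalidInputError("latitude bounds must lie in [-90, 90]")
    if cell_km <= 0:
        raise InvalidInputError("cell_km must be positive")

    # x spans R * dlambda, y spans R * dsin(phi)
    width_km = radius_km * np.radians(lon_max - lon_min)
    sin_lo, sin_hi = np.sin(np.radians([lat_min, lat_max]))
    height_km = radius_km * (sin_hi - sin_lo)
    n_cols = max(1, int(round(width_km / cell_km)))
    n_rows = max(1, int(round(height_km / cell_km)))

    lon_edges = np.linspace(lon_min, lon_max, n_cols + 1)
    sin_edges = np.linspace(sin_lo, sin_hi, n_rows + 1)
    lon = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    lat = np.degrees(np.arcsin(0.5 * (sin_edges[:-1] + sin_edges[1:])))

    grid = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_km=cell_km, lat=lat, lon=lon)
    grid._sin_edges = sin_edges
    grid._lon_edges = lon_edges
    return grid
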