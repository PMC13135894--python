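"""Gridded temperature and suitability containers.

Grids are regular lat/lon rasters (geographic coordinates, WGS84 /
EPSG:4326) addressed by cell centers, stored north-up as numpy arrays of
shape ``(n_lat, n_lon)`` with latitude decreasing along axis 0. Monthly
stacks carry 12 layers. Invalid cells are encoded as NaN in memory and as
the ``NODATA`` sentinel on disk.

On-disk format is NetCDF (via xarray's scipy backend): variables
``temperature(month, lat, lon)`` (°C) and ``land_mask(lat, lon)``
(1 = land, 0 = sea), with a ``units`` attribute on temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

NODATA = -9999.0
EARTH_RADIUS_KM = 6371.0


class AlignmentError(ValueError):
    """Two grids that must share a common raster definition do not."""


@dataclass(frozen=True)
class GridDefinition:
    """Regular geographic grid; ``lats``/``lons`` are cell-center coordinates."""

    lats: np.ndarray  # decreasing, degrees north
    lons: np.ndarray  # increasing, degrees east

    def __post_init__(self):
        lats = np.asarray(self.lats, float)
        lons = np.asarray(self.lons, float)
        if lats.ndim != 1 or lons.ndim != 1 or lats.size == 0 or lons.size == 0:
            raise ValueError("grid axes must be non-empty 1-D arrays")
        if np.any(np.abs(lats) > 90.0):
            raise ValueError("latitudes must lie within [-90, 90]")
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lats.size, self.lons.size

    @property
    def cell_size(self) -> tuple[float, float]:
        dlat = float(np.abs(np.diff(self.lats)).mean()) if self.lats.size > 1 else 1.0
        dlon = float(np.abs(np.diff(self.lons)).mean()) if self.lons.size > 1 else 1.0
        return dlat, dlon

    def aligned_with(self, other: "GridDefinition", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lats, other.lats, atol=tol)
            and np.allclose(self.lons, other.lons, atol=tol)
        )

    def require_aligned(self, other: "GridDefinition") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                "grids are not aligned (shape or cell-center coordinates differ); "
                "resample explicitly before combining"
            )

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell area on a spherical Earth, broadcast to grid shape.

        Area is proportional to cos(latitude of the cell center); absolute
        units are km² for radius 6371 km.
        """
        dlat, dlon = self.cell_size
        row = (
            EARTH_RADIUS_KM**2
            * np.radians(dlat)
            * np.radians(dlon)
            * np.cos(np.radians(self.lats))
        )
        return np.repeat(row[:, None], self.lons.size, axis=1)


@dataclass(frozen=True)
class TemperatureGridStack:
    """12 monthly °C layers plus validity and land/sea masks."""

    grid: GridDefinition
    months: np.ndarray  # (12, n_lat, n_lon), NaN = nodata
    land_mask: np.ndarray  # bool (n_lat, n_lon), True = land

    def __post_init__(self):
        months = np.asarray(self.months, float)
        land = np.asarray(self.land_mask, bool)
        if months.shape != (12, *self.grid.shape):
            raise ValueError(
                f"expected 12 monthly layers of shape {self.grid.shape}, got {months.shape}"
            )
        if land.shape != self.grid.shape:
            raise ValueError("land mask shape does not match grid")
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "land_mask", land)

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells with data in every month."""
        return np.all(np.isfinite(self.months), axis=0)

    def realm_mask(self, realm: str) -> np.ndarray:
        """Cells ecologically relevant for a realm: sea for marine species,
        land for freshwater and terrestrial species."""
        if realm == "marine":
            return ~self.land_mask
        if realm in ("freshwater", "terrestrial"):
            return self.land_mask
        raise ValueError(f"unknown realm {realm!r}")

    def to_dataset(self) -> xr.Dataset:
        temp = np.where(np.isfinite(self.months), self.months, NODATA)
        return xr.Dataset(
            {
                "temperature": (
                    ("month", "lat", "lon"),
                    temp.astype(np.float32),
                    {"units": "degC", "nodata": NODATA},
                ),
                "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
            },
            coords={
                "month": np.arange(1, 13),
                "lat": self.grid.lats,
                "lon": self.grid.lons,
            },
            attrs={"crs": "EPSG:4326"},
        )

    def save(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "TemperatureGridStack":
        if "temperature" not in ds:
            raise ValueError("dataset lacks a 'temperature' variable")
        if "units" not in ds["temperature"].attrs:
            raise ValueError("temperature variable lacks a units attribute")
        if ds["temperature"].attrs["units"] not in ("degC", "celsius", "C"):
            raise ValueError(
                f"temperature units must be Celsius, got {ds['temperature'].attrs['units']!r}"
            )
        if ds.sizes.get("month") != 12:
            raise ValueError(f"expected 12 monthly layers, got {ds.sizes.get('month')}")
        temp = np.asarray(ds["temperature"].values, float)
        temp = np.where(temp <= NODATA + 0.5, np.nan, temp)
        land = np.asarray(ds["land_mask"].values).astype(bool)
        grid = GridDefinition(np.asarray(ds["lat"].values), np.asarray(ds["lon"].values))
        return cls(grid=grid, months=temp, land_mask=land)

    @classmethod
    def load(cls, path) -> "TemperatureGridStack":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass(frozen=True)
class THSGrid:
    """Annual-mean thermal habitat suitability per cell, in [0, 1] or NaN."""

    grid: GridDefinition
    values: np.ndarray  # (n_lat, n_lon), NaN = nodata

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != self.grid.shape:
            raise ValueError("THS values shape does not match grid")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("unmasked THS values must lie within [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_dataset(self, name: str = "ths") -> xr.Dataset:
        vals = np.where(np.isfinite(self.values), self.values, NODATA)
        return xr.Dataset(
            {name: (("lat", "lon"), vals.astype(np.float32), {"nodata": NODATA})},
            coords={"lat": self.grid.lats, "lon": self.grid.lons},
            attrs={"crs": "EPSG:4326"},
        )

    def save(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path) -> "THSGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        vals = np.asarray(ds["ths"].values, float)
        vals = np.where(vals <= NODATA + 0.5, np.nan, vals)
        grid = GridDefinition(np.asarray(ds["lat"].values), np.asarray(ds["lon"].values))
        return cls(grid=grid, values=vals)
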